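"""Scene generator: duct profile, inlet patterns, scalar transport."""

import numpy as np
import pytest

from angioflow import flow_scene as fs


@pytest.fixture(scope="module")
def geometry():
    return fs.DuctGeometry()


# ---------------------------------------------------------------------------
# duct velocity profile


def poisson_duct_oracle(n=64):
    """Finite-difference solve of -lap(v) = 1 with no-slip walls.

    Independent oracle for the series solution: 5-point Laplacian on an
    n x n interior grid over the unit square cross-section, solved with a
    sparse direct factorization, then normalized to unit mean.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    h = 1.0 / (n + 1)
    main = sp.diags([-1, 4, -1], [-1, 0, 1], shape=(n, n))
    eye = sp.identity(n)
    A = (sp.kron(eye, main) + sp.kron(sp.diags([-1, -1], [-1, 1],
                                               shape=(n, n)), eye)) / h**2
    v = spla.spsolve(A.tocsc(), np.ones(n * n)).reshape(n, n)
    return v / v.mean()


def test_centerline_to_bulk_ratio(geometry):
    """Square-duct centreline velocity is ~2.096x the bulk mean."""
    v = fs.duct_series_velocity(geometry, 1.0, np.array([0.0]), np.array([0.0]),
                                n_terms=100)
    assert v[0, 0] == pytest.approx(2.096, abs=5e-3)


def test_profile_matches_poisson_oracle(geometry):
    """Series solution agrees with an FD Poisson solve to rel-L2 < 1e-3."""
    n = 64
    a = geometry.side_length
    coords = (np.arange(1, n + 1)) * a / (n + 1) - a / 2
    v_series = fs.duct_series_velocity(geometry, 1.0, coords, coords, n_terms=100)
    v_fd = poisson_duct_oracle(n)
    # both normalized to unit mean over the same interior nodes
    v_series = v_series / v_series.mean()
    v_fd = v_fd / v_fd.mean()
    rel = np.linalg.norm(v_series - v_fd) / np.linalg.norm(v_fd)
    assert rel < 1e-3


def test_no_slip_and_symmetry(geometry):
    a = geometry.side_length
    x = np.linspace(-a / 2, a / 2, 9)
    v = fs.duct_series_velocity(geometry, 1.0, x, x, n_terms=80)
    assert np.allclose(v[0, :], 0.0, atol=1e-12)      # x = -a/2 wall
    assert np.allclose(v[-1, :], 0.0, atol=1e-12)
    assert np.allclose(v[:, 0], 0.0, atol=1e-12)      # z walls
    assert np.allclose(v, v[::-1, :], atol=1e-12)     # x -> -x
    assert np.allclose(v, v[:, ::-1], atol=1e-12)     # z -> -z


def test_invalid_geometry_rejected():
    with pytest.raises(fs.InvalidGeometryError):
        fs.DuctGeometry(side_length=-1.0)
    with pytest.raises(ValueError):
        fs.duct_series_velocity(fs.DuctGeometry(), -0.1, np.zeros(1), np.zeros(1))


# ---------------------------------------------------------------------------
# inlet boundary condition


def test_radial_cosine_concentration_values():
    """Radial cosine profile: 1.0 on the axis, 0.54 at the 2 mm rim."""
    spec = fs.InletSpec(case_id=3)
    assert fs.inlet_concentration(spec, 0.05, 0.0) == pytest.approx(1.0)
    assert fs.inlet_concentration(spec, 0.05, 0.002) == pytest.approx(0.54, abs=0.005)


def test_temporal_cosine_concentration():
    spec = fs.InletSpec(case_id=4)
    assert fs.inlet_concentration(spec, 0.0, 0.001) == pytest.approx(1.0)
    # negative half-period clips to zero (no dye extracted)
    assert fs.inlet_concentration(spec, 0.75, 0.001) == 0.0
    # period of the temporal cosine is 1.5 s
    assert 2 * np.pi / spec.temporal_omega == pytest.approx(1.5)


def test_intermittent_schedule():
    spec = fs.InletSpec(case_id=2)
    assert spec.period == pytest.approx(0.35)
    assert spec.is_injecting(0.36)        # 0.36 mod 0.35 = 0.01 < 0.1
    assert not spec.is_injecting(0.2)     # inside the 0.25 s pause


def test_inlet_radius_ramp():
    spec = fs.InletSpec(case_id=1, ramp_duration=1.0)
    assert fs.inlet_radius(spec, 0.0) == pytest.approx(0.00037)
    assert fs.inlet_radius(spec, 1.0) == pytest.approx(0.002)
    assert fs.inlet_radius(spec, 5.0) == pytest.approx(0.002)
    assert fs.inlet_radius(spec, 0.5) == pytest.approx(0.001185)
    # other cases hold the radius constant
    assert fs.inlet_radius(fs.InletSpec(case_id=2), 0.0) == pytest.approx(0.002)


def test_unknown_case_rejected():
    with pytest.raises(ValueError):
        fs.InletSpec(case_id=5)


# ---------------------------------------------------------------------------
# transport


def _blob_volume(n=32, sigma=0.1, center=(0.5, 0.4, 0.5)):
    x = np.linspace(0.0, 1.0, n)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r2 = sum((G - c) ** 2 for G, c in zip((X, Y, Z), center))
    phi = 0.8 * np.exp(-r2 / (2 * sigma**2))
    return fs.ConcentrationVolume(phi=phi, x=x, y=x, z=x, timestamp=0.0)


def _uniform_flow(vol, v0):
    return fs.FlowField(x=vol.x, z=vol.z, v=np.full((vol.x.size, vol.z.size), v0),
                        bulk_velocity=max(v0, 1e-12), geometry=fs.DuctGeometry(1.0, 1.0))


def test_identity_dynamics():
    """Zero velocity and zero diffusivity leave the field untouched."""
    vol = _blob_volume()
    out = fs.transport_step(vol, _uniform_flow(vol, 0.0), None, 0.1, 0.0)
    assert np.allclose(out.phi, vol.phi, atol=1e-12)


def test_advected_gaussian_matches_translation():
    """Uniform flow displaces a Gaussian blob by v*dt."""
    vol = _blob_volume()
    dy = vol.y[1] - vol.y[0]
    v0, dt = 0.8 * dy / 0.1, 0.1            # 0.8-cell displacement
    out = fs.transport_step(vol, _uniform_flow(vol, v0), None, dt, 0.0)
    x = vol.x
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r2 = (X - 0.5) ** 2 + (Y - 0.4 - v0 * dt) ** 2 + (Z - 0.5) ** 2
    expected = 0.8 * np.exp(-r2 / (2 * 0.1**2))
    assert np.max(np.abs(out.phi - expected)) < 0.01 * expected.max()


def test_diffused_gaussian_variance_growth():
    """Variance along each axis grows by 2*D*dt per step within 5%."""
    vol = _blob_volume(n=48, sigma=0.08)
    dx = vol.x[1] - vol.x[0]
    dt = 0.1
    D = 0.1 * dx**2 / dt                     # alpha = 0.1, comfortably stable
    def var_y(phi):
        m = phi.sum()
        yc = (phi.sum(axis=(0, 2)) * vol.y).sum() / m
        return (phi.sum(axis=(0, 2)) * (vol.y - yc) ** 2).sum() / m
    v0 = var_y(vol.phi)
    out = vol
    for _ in range(5):
        out = fs.transport_step(out, _uniform_flow(vol, 0.0), None, dt, D)
    growth = var_y(out.phi) - v0
    assert growth == pytest.approx(2 * D * dt * 5, rel=0.05)


def test_diffusion_stability_guard():
    vol = _blob_volume(n=16)
    dx = vol.x[1] - vol.x[0]
    with pytest.raises(fs.StabilityError):
        fs.transport_step(vol, _uniform_flow(vol, 0.0), None, 1.0, dx**2)


def test_grid_mismatch_rejected():
    vol = _blob_volume(n=16)
    bad_flow = fs.FlowField(x=vol.x[:8], z=vol.z[:8], v=np.zeros((8, 8)),
                            bulk_velocity=1.0, geometry=fs.DuctGeometry(1.0, 1.0))
    with pytest.raises(ValueError):
        fs.transport_step(vol, bad_flow, None, 0.1, 0.0)


# ---------------------------------------------------------------------------
# case runs


@pytest.fixture(scope="module")
def short_runs():
    cfg = fs.SceneConfig(nx=32, ny=64, nz=32)
    return {
        1: fs.run_case(1, cfg, duration=1.25, export_interval=0.2),
        3: fs.run_case(3, cfg, duration=0.65, export_interval=0.2),
    }


def test_concentration_bounds(short_runs):
    for seq in short_runs.values():
        for snap in seq.snapshots:
            assert snap.phi.min() >= 0.0
            assert snap.phi.max() <= 1.0


def test_mass_balance_closed_run(short_runs):
    """Injected minus outflowed dye mass matches the inventory change.

    The semi-Lagrangian scheme is not exactly conservative; the
    continuous-injection run must close within 1%, the pulsed run (two
    persistent sharp bolus fronts) within 2.5%.
    """
    m1 = short_runs[1].mass_report
    assert abs(m1["imbalance"]) / m1["influx"] < 0.01
    m3 = short_runs[3].mass_report
    assert abs(m3["imbalance"]) / m3["influx"] < 0.025


def test_export_schedule_pairing(short_runs):
    """Every interval export has exactly one companion 0.02 s later."""
    for seq in short_runs.values():
        assert len(seq.snapshots) == 2 * len(seq.pairs)
        ts = seq.timestamps
        assert np.all(np.diff(ts) > 0)
        for ia, ib in seq.pairs:
            assert ts[ib] - ts[ia] == pytest.approx(0.02, abs=1e-9)


def test_quarter_domain_matches_full():
    """Quarter-domain run with mirroring reproduces the full domain."""
    kw = dict(duration=0.45, export_interval=0.2)
    qcfg = fs.SceneConfig(nx=16, ny=32, nz=16, quarter=True)
    fcfg = fs.SceneConfig(nx=16, ny=32, nz=16, quarter=False)
    qseq = fs.run_case(4, qcfg, **kw)
    fseq = fs.run_case(4, fcfg, **kw)
    for qs, fsnap in zip(qseq.snapshots, fseq.snapshots):
        mirrored = fs.mirror_quarter(qs.phi)
        # the cubic-spline prefilter sees an array edge at the symmetry
        # plane instead of mirrored data, leaving O(1e-6) differences
        assert np.allclose(mirrored, fsnap.phi, atol=1e-4)


def test_default_schedule_yields_53_pairs():
    """The four default case schedules export 106 snapshots / 53 pairs."""
    dt = fs.SceneConfig().dt_sim
    total_pairs = 0
    for case, (duration, interval) in fs.CASE_DEFAULTS.items():
        k = int((duration - 0.02) / interval)
        total_pairs += k
    assert total_pairs == 53
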