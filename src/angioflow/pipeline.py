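"""End-to-end pipeline: simulate -> project -> optical flow -> dataset ->
train -> evaluate, with on-disk stage outputs and provenance sidecars.

Every stage writes a JSON sidecar carrying the config hash and seed, and
refuses (without ``force``) to consume inputs produced under a different
config hash.  All randomness flows through named seeds derived from the
single pipeline seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset as ds
from . import evaluation as ev
from . import flow_scene as fsc
from . import ofm as ofm_mod
from . import projector as pj
from . import regressors as rg

log = logging.getLogger("angioflow")

STAGE_VERSION = "1"


@dataclass
class DatasetSection:
    threshold: int = ds.DEFAULT_THRESHOLD
    singleton_policy: str = "train"


@dataclass
class TrainSection:
    """Model grid and the desk-scale training schedule.

    ``subsample`` caps the rows used by the iterative network fits (per
    fold and for the final fit); fold scoring always uses the entire
    validation fold.
    """

    models: tuple = ("lasso", "mlp", "cnn", "lstm")
    losses: tuple = ("mae", "mse")
    k_folds: int = 10
    repeats: int = 3
    l1_penalty: float = 1e-3
    mlp: dict = field(default_factory=lambda: dict(
        epochs=100, batch_size=32, learning_rate=1e-3, subsample=4000))
    cnn: dict = field(default_factory=lambda: dict(
        epochs=150, batch_size=128, learning_rate=3e-3, subsample=3000))
    lstm: dict = field(default_factory=lambda: dict(
        epochs=120, batch_size=128, learning_rate=3e-3, subsample=3000))


@dataclass
class EvalSection:
    stations: tuple = ev.DEFAULT_STATIONS
    definition: str = "D1"
    headline_model: str = "mlp"
    headline_loss: str = "mae"


@dataclass
class PipelineConfig:
    scene: fsc.SceneConfig = field(default_factory=fsc.SceneConfig)
    cases: tuple = (1, 2, 3, 4)
    durations: dict = field(default_factory=dict)     # case -> s, else defaults
    imaging: pj.ImagingConfig = field(default_factory=pj.ImagingConfig)
    ofm: ofm_mod.OFMConfig = field(default_factory=ofm_mod.OFMConfig)
    dataset: DatasetSection = field(default_factory=DatasetSection)
    train: TrainSection = field(default_factory=TrainSection)
    evaluation: EvalSection = field(default_factory=EvalSection)
    seed: int = 0

    def __post_init__(self):
        for c in self.cases:
            if c not in (1, 2, 3, 4):
                raise ValueError(f"case ids must be in 1..4, got {c}")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scene"]["geometry"] = asdict(self.scene.geometry)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        scene = dict(d.pop("scene", {}))
        geom = fsc.DuctGeometry(**scene.pop("geometry", {}))
        kw = dict(
            scene=fsc.SceneConfig(geometry=geom, **scene),
            imaging=pj.ImagingConfig(**d.pop("imaging", {})),
            ofm=ofm_mod.OFMConfig(**d.pop("ofm", {})),
            dataset=DatasetSection(**d.pop("dataset", {})),
            train=TrainSection(**d.pop("train", {})),
            evaluation=EvalSection(**d.pop("evaluation", {})),
        )
        if "cases" in d:
            kw["cases"] = tuple(d.pop("cases"))
        if "durations" in d:
            kw["durations"] = {int(k): v for k, v in d.pop("durations", {}).items()}
        if "seed" in d:
            kw["seed"] = d.pop("seed")
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def derived_seed(self, name: str) -> int:
        """Stable per-purpose seed below 2**31."""
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def default_config(seed: int = 0) -> PipelineConfig:
    """The packaged four-case desk-scale configuration."""
    return PipelineConfig(seed=seed)


def fixture_config(seed: int = 0) -> PipelineConfig:
    """Miniature configuration for fast tests: coarse grid, short runs."""
    return PipelineConfig(
        scene=fsc.SceneConfig(nx=32, ny=64, nz=32),
        durations={1: 1.25, 2: 0.65, 3: 0.65, 4: 0.65},
        # darker attenuation calibration: the coarse fixture grid feathers
        # the jet rim over a full cell, thinning the projected column
        imaging=pj.ImagingConfig(width_px=81, height_px=154, mu_ref=900.0),
        ofm=ofm_mod.OFMConfig(pitch_x=0.0254 / 81, pitch_y=0.0254 / 154,
                              max_iter=400),
        train=TrainSection(
            mlp=dict(epochs=30, batch_size=32, learning_rate=1e-3, subsample=1500),
            cnn=dict(epochs=40, batch_size=128, learning_rate=3e-3, subsample=1000),
            lstm=dict(epochs=30, batch_size=128, learning_rate=3e-3, subsample=1000),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sidecar helpers


def _write_sidecar(path: Path, config: PipelineConfig, stage: str, **extra):
    meta = {"stage": stage, "stage_version": STAGE_VERSION,
            "config_hash": config.config_hash(), "seed": config.seed, **extra}
    path.write_text(json.dumps(meta, indent=1, default=str))


def _check_sidecar(path: Path, config: PipelineConfig, force: bool):
    if not path.exists():
        raise FileNotFoundError(f"missing stage sidecar {path}")
    meta = json.loads(path.read_text())
    if meta.get("config_hash") != config.config_hash() and not force:
        raise RuntimeError(
            f"stage output {path} was produced under config hash "
            f"{meta.get('config_hash')} != {config.config_hash()}; "
            "rerun the stage or pass --force")
    return meta


# ---------------------------------------------------------------------------
# stages


def cmd_simulate(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the scene generator for every configured case."""
    t0 = time.perf_counter()
    sequences = {}
    for case in config.cases:
        duration = config.durations.get(case)
        sequences[case] = fsc.run_case(case, config.scene, duration=duration)
        log.info("simulated case %d: %d snapshots, %d pairs", case,
                 len(sequences[case].snapshots), len(sequences[case].pairs))
    if outdir is not None:
        outdir = Path(outdir)
        for case, seq in sequences.items():
            d = outdir / f"case{case}"
            d.mkdir(parents=True, exist_ok=True)
            vol0 = seq.snapshots[0]
            np.savez_compressed(
                d / "scene.npz",
                phi=np.stack([s.phi for s in seq.snapshots]).astype(np.float32),
                timestamps=seq.timestamps,
                x=vol0.x, y=vol0.y, z=vol0.z,
                flow_v=seq.flow.v,
                pairs=np.array(seq.pairs, dtype=int),
            )
            _write_sidecar(d / "scene.json", config, "simulate", case=case,
                           export_interval=seq.export_interval,
                           n_snapshots=len(seq.snapshots),
                           mass_report=seq.mass_report)
    log.info("simulate stage done in %.1f s", time.perf_counter() - t0)
    return sequences


def load_scenes(config: PipelineConfig, outdir: str | Path,
                force: bool = False) -> dict:
    outdir = Path(outdir)
    sequences = {}
    for case in config.cases:
        d = outdir / f"case{case}"
        _check_sidecar(d / "scene.json", config, force)
        with np.load(d / "scene.npz") as z:
            x, y, zc = z["x"], z["y"], z["z"]
            snaps = [fsc.ConcentrationVolume(phi=p.astype(float), x=x, y=y, z=zc,
                                             timestamp=float(t))
                     for p, t in zip(z["phi"], z["timestamps"])]
            flow = fsc.duct_velocity_profile(config.scene.geometry,
                                             config.scene.bulk_velocity,
                                             config.scene.n_terms, x, zc)
            meta = json.loads((d / "scene.json").read_text())
            sequences[case] = fsc.SceneSequence(
                case_id=case, config=config.scene,
                inlet=fsc.make_inlet_spec(case, config.scene), flow=flow,
                snapshots=snaps,
                pairs=[tuple(p) for p in z["pairs"]],
                export_interval=meta["export_interval"])
    return sequences


def cmd_project(config: PipelineConfig, sequences: dict,
                outdir: str | Path | None = None) -> dict:
    """Render all snapshots of every case to 8-bit projections."""
    t0 = time.perf_counter()
    images = {}
    for case, seq in sequences.items():
        images[case] = [pj.render_projection(s, config.imaging,
                                             quarter=config.scene.quarter)
                        for s in seq.snapshots]
        if outdir is not None:
            d = Path(outdir) / f"case{case}"
            d.mkdir(parents=True, exist_ok=True)
            for i, img in enumerate(images[case]):
                img.save(d / f"frame_{i:03d}.png", meta={"case": case})
            _write_sidecar(d / "project.json", config, "project", case=case,
                           n_images=len(images[case]))
    log.info("project stage done in %.1f s", time.perf_counter() - t0)
    return images


def load_images(config: PipelineConfig, outdir: str | Path,
                force: bool = False) -> dict:
    images = {}
    for case in config.cases:
        d = Path(outdir) / f"case{case}"
        _check_sidecar(d / "project.json", config, force)
        paths = sorted(d.glob("frame_*.png"))
        images[case] = [pj.ProjectiveImage.load(p) for p in paths]
    return images


def cmd_ofm(config: PipelineConfig, sequences: dict, images: dict,
            outdir: str | Path | None = None) -> dict:
    """Optical-flow analysis of every export pair."""
    t0 = time.perf_counter()
    fields = {}
    for case, seq in sequences.items():
        imgs = images[case]
        if len(imgs) % 2 != 0 and not seq.pairs:
            raise ValueError(
                f"case {case}: odd number of images ({len(imgs)}) with no "
                f"pairing metadata; orphan frame index {len(imgs) - 1}")
        case_fields = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ofm_mod.ConvergenceWarning)
            for ia, ib in seq.pairs:
                case_fields.append(ofm_mod.estimate_flow(imgs[ia], imgs[ib],
                                                         config.ofm))
        fields[case] = case_fields
        if outdir is not None:
            d = Path(outdir) / f"case{case}"
            d.mkdir(parents=True, exist_ok=True)
            for k, ((ia, ib), fld) in enumerate(zip(seq.pairs, case_fields)):
                img = imgs[ia]
                h, w = fld.u.shape
                ii, jj = np.mgrid[0:h, 0:w]
                pd.DataFrame({
                    "pixel_i": ii.ravel(), "pixel_j": jj.ravel(),
                    "x_m": img.x[jj.ravel()], "y_m": img.y[ii.ravel()],
                    "u_ofm": fld.u.ravel(), "v_ofm": fld.v.ravel(),
                    "Ix": fld.ix.ravel(), "Iy": fld.iy.ravel(),
                }).to_csv(d / f"ofm_{k:03d}.csv", index=False)
            _write_sidecar(d / "ofm.json", config, "ofm", case=case,
                           n_pairs=len(case_fields))
    log.info("ofm stage done in %.1f s", time.perf_counter() - t0)
    return fields


def cmd_build(config: PipelineConfig, sequences: dict, images: dict,
              fields: dict, outdir: str | Path | None = None) -> pd.DataFrame:
    """Assemble the masked sample table and apply the duplicate split."""
    t0 = time.perf_counter()
    tables = []
    for case, seq in sequences.items():
        first_frames = [images[case][ia] for ia, _ in seq.pairs]
        tables.append(ds.assemble_samples(
            seq, first_frames, fields[case],
            threshold=config.dataset.threshold))
    table = pd.concat(tables, ignore_index=True)
    table = ds.split_by_duplicates(table, seed=config.derived_seed("split"),
                                   singleton_policy=config.dataset.singleton_policy)
    log.info("build stage: %d records (%d train / %d test) in %.1f s",
             len(table), (table["split"] == "train").sum(),
             (table["split"] == "test").sum(), time.perf_counter() - t0)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "samples.csv", index=False)
        _write_sidecar(outdir / "samples.json", config, "build",
                       threshold=config.dataset.threshold,
                       n_records=len(table),
                       n_train=int((table["split"] == "train").sum()),
                       n_test=int((table["split"] == "test").sum()))
    return table


def load_table(config: PipelineConfig, outdir: str | Path,
               force: bool = False) -> pd.DataFrame:
    _check_sidecar(Path(outdir) / "samples.json", config, force)
    return pd.read_csv(Path(outdir) / "samples.csv")


def _model_config(config: PipelineConfig, kind: str, loss: str) -> rg.ModelConfig:
    tr = config.train
    seed = config.derived_seed(f"model:{kind}:{loss}")
    if kind == "lasso":
        return rg.ModelConfig(kind="lasso", l1_penalty=tr.l1_penalty,
                              loss=loss, seed=seed)
    sched = getattr(tr, kind)
    return rg.ModelConfig(kind=kind, loss=loss, seed=seed,
                          epochs=sched["epochs"], batch_size=sched["batch_size"],
                          learning_rate=sched["learning_rate"])


def cmd_train(config: PipelineConfig, table: pd.DataFrame,
              outdir: str | Path | None = None):
    """Cross-validate and fit every configured (model, loss) combination."""
    t0 = time.perf_counter()
    train_rows = table[table["split"] == "train"]
    models = {}
    all_scores = []
    for kind in config.train.models:
        for loss in config.train.losses:
            mc = _model_config(config, kind, loss)
            sub = None if kind == "lasso" else getattr(config.train, kind)["subsample"]
            scores = rg.cross_validate(mc, train_rows, k=config.train.k_folds,
                                       repeats=config.train.repeats,
                                       seed=config.derived_seed(f"cv:{kind}:{loss}"),
                                       subsample=sub)
            model = rg.fit_model(train_rows, mc, subsample=sub)
            model.cv_scores = scores
            models[(kind, loss)] = model
            all_scores.append(scores)
            log.info("trained %s/%s: CV MAE %.3e in %.1f s", kind, loss,
                     scores["mae"].mean(), time.perf_counter() - t0)
    cv_scores = pd.concat(all_scores, ignore_index=True)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cv_scores.to_csv(outdir / "cv_scores.csv", index=False)
        for (kind, loss), model in models.items():
            model.save(outdir / f"model_{kind}_{loss}.npz")
        _write_sidecar(outdir / "train.json", config, "train",
                       models=[f"{k}/{l}" for k, l in models])
    return models, cv_scores


def cmd_evaluate(config: PipelineConfig, models: dict, cv_scores: pd.DataFrame,
                 table: pd.DataFrame, outdir: str | Path | None = None) -> dict:
    """Station error profiles, headline comparisons and the report grid."""
    ecfg = config.evaluation
    headline = models[(ecfg.headline_model, ecfg.headline_loss)]

    test_rows = table[table["split"] == "test"]
    estimates = {"ofm": test_rows["v_ofm"].to_numpy(),
                 ecfg.headline_model: headline.predict(test_rows)[:, 1]}
    profile = ev.v_error_profile(test_rows, estimates, y_stations=ecfg.stations,
                                 definition=ecfg.definition)

    report = ev.summarize_run(cv_scores, profile)

    # held-out MAE of every model vs the raw optical-flow input
    truth = test_rows[ds.TARGET_COLUMNS].to_numpy()
    raw = test_rows[["u_ofm", "v_ofm"]].to_numpy()
    report["test_mae_ofm_raw"] = ev.mae(raw, truth)
    for (kind, loss), model in models.items():
        report[f"test_mae_{kind}_{loss}"] = ev.mae(model.predict(test_rows), truth)
        report[f"test_mse_{kind}_{loss}"] = ev.mse(model.predict(test_rows), truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report["table"].to_csv(outdir / "report.csv", index=False)
        profile.to_frame().to_csv(outdir / "error_profile.csv", index=False)
        (outdir / "summary.txt").write_text(ev.format_report(report))
        _write_sidecar(outdir / "evaluate.json", config, "evaluate")
    return report


@dataclass
class RunResult:
    config: PipelineConfig
    sequences: dict
    images: dict
    fields: dict
    table: pd.DataFrame
    models: dict
    cv_scores: pd.DataFrame
    report: dict


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> RunResult:
    """Chain all stages deterministically under the config's seeds."""
    config = config or default_config()
    out = Path(outdir) if outdir is not None else None

    def sub(name):
        return None if out is None else out / name

    sequences = cmd_simulate(config, sub("scenes"))
    images = cmd_project(config, sequences, sub("images"))
    fields = cmd_ofm(config, sequences, images, sub("ofm"))
    table = cmd_build(config, sequences, images, fields, sub("dataset"))
    models, cv_scores = cmd_train(config, table, sub("models"))
    report = cmd_evaluate(config, models, cv_scores, table, sub("evaluation"))
    return RunResult(config=config, sequences=sequences, images=images,
                     fields=fields, table=table, models=models,
                     cv_scores=cv_scores, report=report)


def make_fixtures(seed: int = 0, outdir: str | Path | None = None):
    """Miniature end-to-end fixture set (coarse grid, all four cases).

    Runs the pipeline through the dataset stage in well under a minute;
    used by the test suite.  Returns (config, sequences, images, fields,
    table).
    """
    config = fixture_config(seed)
    sequences = cmd_simulate(config, None if outdir is None else Path(outdir) / "scenes")
    images = cmd_project(config, sequences,
                         None if outdir is None else Path(outdir) / "images")
    fields = cmd_ofm(config, sequences, images,
                     None if outdir is None else Path(outdir) / "ofm")
    table = cmd_build(config, sequences, images, fields,
                      None if outdir is None else Path(outdir) / "dataset")
    for case, imgs in images.items():
        if not any(ds.dye_mask(i, config.dataset.threshold).any() for i in imgs):
            raise AssertionError(f"fixture case {case} produced an empty dye mask")
    return config, sequences, images, fields, table
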