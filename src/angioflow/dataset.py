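"""Supervised-sample assembly from optical-flow fields and ground truth.

Selects dye-dominant pixels (gray <= 80), joins the optical-flow features
``(u_ofm, v_ofm, Ix, Iy)`` with centre-plane ground-truth velocities, and
performs the duplicate-coordinate train/test split: each pixel coordinate
observed at several time instances contributes one randomly chosen record
to the test set and the rest to training, so every test coordinate is
covered by training data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .flow_scene import SceneSequence
from .ofm import OFMField
from .projector import ProjectiveImage

__all__ = [
    "dye_mask",
    "assemble_samples",
    "split_by_duplicates",
    "FEATURE_COLUMNS",
    "TARGET_COLUMNS",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 80
FEATURE_COLUMNS = ["u_ofm", "v_ofm", "Ix", "Iy"]
TARGET_COLUMNS = ["u_truth", "v_truth"]


def dye_mask(image: ProjectiveImage | np.ndarray,
             threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean mask of dye-dominant pixels (gray level <= threshold)."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    gray = image.gray if isinstance(image, ProjectiveImage) else np.asarray(image)
    return gray <= threshold


def centerplane_truth_interpolator(sequence: SceneSequence):
    """Bilinear interpolator of the centre-plane (u, v) ground truth.

    The truth is tabulated on the scene's lateral grid (mirrored to the
    full width) and is streamwise-invariant for the substitute profile;
    it is exposed on an (x, y) grid so callers sample it like any other
    planar field.
    """
    from .flow_scene import mirror_axis

    vol = sequence.snapshots[0] if sequence.snapshots else None
    if vol is None:
        raise ValueError("sequence has no snapshots to define the truth grid")
    if sequence.config.quarter:
        x_grid = mirror_axis(vol.x)
    else:
        x_grid = vol.x
    y_grid = vol.y
    _, v_line = sequence.centerplane_velocity(x_grid)
    v_plane = np.tile(v_line[:, None], (1, y_grid.size))
    u_plane = np.zeros_like(v_plane)
    ui = RegularGridInterpolator((x_grid, y_grid), u_plane, bounds_error=False,
                                 fill_value=None)
    vi = RegularGridInterpolator((x_grid, y_grid), v_plane, bounds_error=False,
                                 fill_value=None)
    return ui, vi


def assemble_samples(
    sequence: SceneSequence,
    images: list[ProjectiveImage],
    ofm_fields: list[OFMField],
    masks: list[np.ndarray] | None = None,
    threshold: int = DEFAULT_THRESHOLD,
    case_label: str | None = None,
) -> pd.DataFrame:
    """One record per masked pixel per image pair.

    ``images`` holds the first frame of each pair (whose mask selects the
    dye-dominant pixels); ground truth is sampled at each pixel centre by
    bilinear interpolation of the centre-plane slice.
    """
    if masks is None:
        masks = [dye_mask(img, threshold) for img in images]
    if not (len(images) == len(ofm_fields) == len(masks)):
        raise ValueError("need one image, OFM field and mask per pair")

    ui, vi = centerplane_truth_interpolator(sequence)
    frames = []
    prefix = case_label or f"case{sequence.case_id}"
    for k, (img, fld, msk) in enumerate(zip(images, ofm_fields, masks)):
        if msk.shape != fld.u.shape or msk.shape != img.gray.shape:
            raise ValueError("mask/field/image shapes inconsistent")
        rows, cols = np.nonzero(msk)
        if rows.size == 0:
            continue
        x = img.x[cols]
        y = img.y[rows]
        pts = np.column_stack([x, y])
        frames.append(pd.DataFrame({
            "pair_id": f"{prefix}_p{k:03d}",
            "timestamp": img.timestamp,
            "pixel_i": rows,
            "pixel_j": cols,
            "x_m": x,
            "y_m": y,
            "u_ofm": fld.u[rows, cols],
            "v_ofm": fld.v[rows, cols],
            "Ix": fld.ix[rows, cols],
            "Iy": fld.iy[rows, cols],
            "u_truth": ui(pts),
            "v_truth": vi(pts),
        }))
    if not frames:
        return pd.DataFrame(columns=["pair_id", "timestamp", "pixel_i", "pixel_j",
                                     "x_m", "y_m", *FEATURE_COLUMNS, *TARGET_COLUMNS])
    table = pd.concat(frames, ignore_index=True)
    if not np.all(np.isfinite(table[FEATURE_COLUMNS + TARGET_COLUMNS].to_numpy())):
        raise ValueError("non-finite values in assembled samples")
    return table


def split_by_duplicates(table: pd.DataFrame, seed: int = 0,
                        singleton_policy: str = "train") -> pd.DataFrame:
    """Label records train/test by the duplicate-coordinate rule.

    Coordinates are keyed on exact pixel indices ``(pixel_i, pixel_j)``.
    For every key with multiplicity m >= 2, one uniformly chosen record
    becomes test and the remaining m - 1 train; singleton keys go to
    train (or are dropped with ``singleton_policy='drop'``).  The split
    is deterministic for a fixed seed.
    """
    if table.empty:
        raise ValueError("cannot split an empty sample table")
    if singleton_policy not in ("train", "drop"):
        raise ValueError("singleton_policy must be 'train' or 'drop'")

    rng = np.random.default_rng(seed)
    out = table.copy()
    perm = rng.permutation(len(out))
    key = out["pixel_i"].to_numpy() * 100000 + out["pixel_j"].to_numpy()
    shuffled_key = key[perm]
    first_of_key = ~pd.Series(shuffled_key).duplicated(keep="first").to_numpy()
    counts = pd.Series(key).value_counts()
    multi = counts[counts >= 2].index
    is_multi = np.isin(shuffled_key, np.asarray(multi))

    split_shuffled = np.where(first_of_key & is_multi, "test", "train")
    split = np.empty(len(out), dtype=object)
    split[perm] = split_shuffled
    out["split"] = split

    if singleton_policy == "drop":
        singleton = ~np.isin(key, np.asarray(multi))
        out = out.loc[~singleton].reset_index(drop=True)
    return out
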