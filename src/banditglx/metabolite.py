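"""Metabolite-table QC and derived quantities.

Operations on tidy metabolite tables (columns: subject, region, block,
metabolite, concentration, crlb_pct):

* reliability filtering by Cramer-Rao lower bound, keeping strictly
  CRLB < 20% (the boundary value 20.0 is excluded);
* referencing concentrations to creatine + phosphocreatine (CrPCr);
* task-related change scores, ``delta = task - preceding rest`` in absolute
  and percent form;
* generalized Dice overlap of binary volume-of-interest masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteEstimate",
    "VoiMask",
    "filter_by_crlb",
    "normalize_to_creatine",
    "delta_glx",
    "generalized_dice",
    "pairwise_mean_dice",
    "load_mask",
]

CREATINE = "CrPCr"


@dataclass(frozen=True)
class MetaboliteEstimate:
    subject_id: str
    region: str
    block: str
    metabolite: str
    concentration: float
    crlb_pct: float

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.crlb_pct < 0:
            raise ValueError("crlb_pct must be >= 0")


def _as_frame(estimates) -> pd.DataFrame:
    if isinstance(estimates, pd.DataFrame):
        return estimates
    return pd.DataFrame([e.__dict__ for e in estimates]).rename(
        columns={"subject_id": "subject"}
    )


def filter_by_crlb(
    estimates, threshold_pct: float = 20.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep rows with CRLB strictly below the threshold.

    Returns ``(retained, exclusion_log)``; the log lists every dropped row
    with its reason.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    df = _as_frame(estimates)
    if df.empty:
        return df.copy(), df.copy()
    keep = df["crlb_pct"] < threshold_pct
    excluded = df[~keep].copy()
    excluded["reason"] = [
        f"CRLB {v:g}% >= {threshold_pct:g}%" for v in excluded["crlb_pct"]
    ]
    return df[keep].copy(), excluded


def normalize_to_creatine(estimates, creatine: str = CREATINE) -> pd.DataFrame:
    """Express every metabolite as a ratio to CrPCr within its
    (subject, region, block) group; the CrPCr ratio is exactly 1."""
    df = _as_frame(estimates).copy()
    keys = ["subject", "region", "block"]
    cr = df[df["metabolite"] == creatine].set_index(keys)["concentration"]
    missing = set(map(tuple, df[keys].drop_duplicates().values)) - set(cr.index)
    if missing:
        raise ValueError(f"groups without a {creatine} reference row: {sorted(missing)}")
    denom = df.set_index(keys).index.map(cr)
    df["ratio"] = df["concentration"].to_numpy() / np.asarray(denom, float)
    df.loc[df["metabolite"] == creatine, "ratio"] = 1.0
    return df


def delta_glx(task_value: float, reference_rest_value: float) -> tuple[float, float]:
    """Task-block minus preceding-rest concentration, absolute and percent."""
    if reference_rest_value <= 0:
        raise ValueError("reference concentration must be positive")
    absolute = task_value - reference_rest_value
    return absolute, 100.0 * absolute / reference_rest_value


@dataclass(frozen=True)
class VoiMask:
    """Binary voxel mask for one subject's volume of interest."""

    subject_id: str
    region: str
    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise ValueError("mask has no positive voxel")
        object.__setattr__(self, "mask", m)


def load_mask(path: str | Path, subject_id: str = "", region: str = "") -> VoiMask:
    """Read a binary NIfTI volume as a VoiMask."""
    import nibabel as nib

    img = nib.load(str(path))
    return VoiMask(subject_id, region, np.asanyarray(img.dataobj) > 0)


def _mask_arrays(masks) -> list[np.ndarray]:
    arrays = [m.mask if isinstance(m, VoiMask) else np.asarray(m, bool) for m in masks]
    if len(arrays) < 2:
        raise ValueError("need at least 2 masks")
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise ValueError(f"mask {i} shape {a.shape} differs from {shape}")
    return arrays


def generalized_dice(masks) -> float:
    """Group-wise overlap: sum over unordered pairs of |A and B| divided by the
    sum over pairs of |A or B| (Crum-style generalized overlap).

    For exactly two masks this is intersection-over-union (the monotone
    analog of classic Dice); identical masks give 1, disjoint masks 0.
    """
    arrays = _mask_arrays(masks)
    inter = 0
    union = 0
    for a, b in combinations(arrays, 2):
        inter += int(np.sum(a & b))
        union += int(np.sum(a | b))
    return inter / union if union else 0.0


def pairwise_mean_dice(masks) -> float:
    """Mean of classic Dice 2|A∩B|/(|A|+|B|) over unordered pairs."""
    arrays = _mask_arrays(masks)
    vals = [
        2 * np.sum(a & b) / (np.sum(a) + np.sum(b)) for a, b in combinations(arrays, 2)
    ]
    return float(np.mean(vals))
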