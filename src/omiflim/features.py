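"""Per-cell OMI feature extraction and quality control.

Pixel fit maps for the two spectral channels are combined with a label image
(one integer label per cell, 0 = background) into a feature table with one
row per cell.  Lifetime variables are unweighted means over the valid fitted
pixels inside the mask; the optical redox ratio is computed at the cell
level from summed raw intensities,

    ORR = sum(I_NADPH) / (sum(I_NADPH) + sum(I_FAD)),

which bounds it in [0, 1] and equals the intensity-weighted mean of
per-pixel ratios.  Four exclusion rules remove records that are unlikely to
be single, well-fit cells: mean NAD(P)H intensity < 10 a.u., mask area
< 70 px, reduced chi-square > 1.3, NAD(P)H tau1 < 350 ps (all strict
inequalities; boundary values are retained).

The per-cell chi-square statistic the QC rule consumes is the mean of the
per-pixel reduced chi-square over valid mask pixels: a 1.3 cutoff presumes
a unit-mean statistic, and the maximum over the hundreds of pixels of a
typical mask exceeds 1.3 even under a correctly specified model (and grows
with cell area).  The per-cell maximum is still reported (``chi2_max``)
and can be selected for the rule via ``apply_qc(rules=...)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import DecayCube, PixelFitMap
from .simulate import OMI_VARIABLES

#: QC rule defaults: (column, comparator, threshold, reason code).
QC_RULES = [
    ("mean_nadph_intensity", "lt", 10.0, "low-intensity"),
    ("area_px", "lt", 70.0, "small-mask"),
    ("chi2_mean", "gt", 1.3, "poor-fit"),
    ("nadph_tau1", "lt", 350.0, "short-tau1"),
]

#: Fixed column order of the exported feature table.
FEATURE_COLUMNS = [
    "cell_id",
    "donor",
    "condition",
    "cell_type",
    "area_px",
    "nadph_tau_m",
    "nadph_tau1",
    "nadph_tau2",
    "nadph_alpha1",
    "fad_tau_m",
    "fad_tau1",
    "fad_tau2",
    "fad_alpha1",
    "orr",
    "mean_nadph_intensity",
    "chi2_mean",
    "chi2_max",
    "valid_pixel_frac",
    "qc_pass",
    "qc_reasons",
]


def load_masks(label_image: np.ndarray) -> tuple[np.ndarray, int]:
    """Validate a label image and re-index labels contiguously from 1.

    Returns the re-indexed image and the number of cells.  Mask generation
    itself (segmentation, manual correction) happens upstream; any integer
    label image is accepted.
    """
    lab = np.asarray(label_image)
    if lab.ndim != 2:
        raise ValueError("label image must be 2-D")
    if not np.issubdtype(lab.dtype, np.integer):
        if not np.allclose(lab, np.round(lab)):
            raise ValueError("label image must be integer-valued")
        lab = np.round(lab).astype(np.int32)
    if lab.min() < 0:
        raise ValueError("labels must be nonnegative")
    old = np.unique(lab)
    old = old[old > 0]
    if len(old) == 0:
        import warnings

        warnings.warn("label image contains no cells", stacklevel=2)
    out = np.zeros_like(lab, dtype=np.int32)
    for new, o in enumerate(old, start=1):
        out[lab == o] = new
    return out, len(old)


@dataclass
class CellRecord:
    """One cell's OMI variables plus QC inputs."""

    cell_id: int
    area_px: int
    nadph_tau_m: float
    nadph_tau1: float
    nadph_tau2: float
    nadph_alpha1: float
    fad_tau_m: float
    fad_tau1: float
    fad_tau2: float
    fad_alpha1: float
    orr: float
    mean_nadph_intensity: float
    chi2_mean: float
    chi2_max: float
    valid_pixel_frac: float
    qc_pass: bool = True
    qc_reasons: str = ""
    donor: str = "na"
    condition: str = "na"
    cell_type: str = "unknown"


def _channel_means(fitmap: PixelFitMap, mask: np.ndarray) -> dict:
    """Unweighted means of fitted lifetime variables over valid mask pixels."""
    sel = mask & fitmap.valid_mask
    if not sel.any():
        return None
    out = {
        "tau_m": float(fitmap.tau_m[sel].mean()),
        "tau1": float(fitmap.tau1[sel].mean()),
        "tau2": float(fitmap.tau2[sel].mean()),
        "alpha1": float(fitmap.alpha1_pct[sel].mean()),
        "chi2_mean": float(np.nanmean(fitmap.chi2_reduced[sel])),
        "chi2_max": float(np.nanmax(fitmap.chi2_reduced[sel])),
        "n_valid": int(sel.sum()),
    }
    return out


def aggregate_cell(
    fitmaps: dict,
    cubes: dict,
    label_image: np.ndarray,
    cell_id: int,
    donor: str = "na",
    condition: str = "na",
    cell_type: str = "unknown",
) -> CellRecord:
    """Collapse one cell's pixels into a :class:`CellRecord`.

    ``fitmaps`` and ``cubes`` map channel names ("nadph", "fad") to
    :class:`PixelFitMap` and :class:`DecayCube`; all grids must coincide
    with the label image (no resampling).  Intensity sums for the redox
    ratio use the raw (unbinned) cubes over all mask pixels; lifetime means
    use valid fitted pixels only, and the record carries that fraction.
    """
    mask = np.asarray(label_image) == cell_id
    area = int(mask.sum())
    if area == 0:
        raise ValueError(f"label {cell_id} not present in label image")
    for ch, fm in fitmaps.items():
        if fm.valid_mask.shape != mask.shape:
            raise ValueError(f"{ch} fit map grid does not match label image")

    sums = {}
    for ch in ("nadph", "fad"):
        cube = cubes[ch]
        counts = cube.counts if isinstance(cube, DecayCube) else np.asarray(cube)
        if counts.shape[:2] != mask.shape:
            raise ValueError(f"{ch} cube grid does not match label image")
        sums[ch] = float(counts.sum(axis=2)[mask].sum())
    denom = sums["nadph"] + sums["fad"]
    orr = sums["nadph"] / denom if denom > 0 else np.nan
    mean_int = sums["nadph"] / area

    ch_stats = {ch: _channel_means(fitmaps[ch], mask) for ch in ("nadph", "fad")}
    if any(v is None for v in ch_stats.values()):
        return CellRecord(
            cell_id=cell_id,
            area_px=area,
            nadph_tau_m=np.nan,
            nadph_tau1=np.nan,
            nadph_tau2=np.nan,
            nadph_alpha1=np.nan,
            fad_tau_m=np.nan,
            fad_tau1=np.nan,
            fad_tau2=np.nan,
            fad_alpha1=np.nan,
            orr=orr,
            mean_nadph_intensity=mean_int,
            chi2_mean=np.nan,
            chi2_max=np.nan,
            valid_pixel_frac=0.0,
            qc_pass=False,
            qc_reasons="no-valid-pixels",
            donor=donor,
            condition=condition,
            cell_type=cell_type,
        )

    n, f = ch_stats["nadph"], ch_stats["fad"]
    return CellRecord(
        cell_id=cell_id,
        area_px=area,
        nadph_tau_m=n["tau_m"],
        nadph_tau1=n["tau1"],
        nadph_tau2=n["tau2"],
        nadph_alpha1=n["alpha1"],
        fad_tau_m=f["tau_m"],
        fad_tau1=f["tau1"],
        fad_tau2=f["tau2"],
        fad_alpha1=f["alpha1"],
        orr=orr,
        mean_nadph_intensity=mean_int,
        chi2_mean=max(n["chi2_mean"], f["chi2_mean"]),
        chi2_max=max(n["chi2_max"], f["chi2_max"]),
        valid_pixel_frac=min(n["n_valid"], f["n_valid"]) / area,
        donor=donor,
        condition=condition,
        cell_type=cell_type,
    )


def build_feature_table(
    fitmaps: dict,
    cubes: dict,
    label_image: np.ndarray,
    donor: str = "na",
    condition: str = "na",
    cell_types: dict | None = None,
) -> pd.DataFrame:
    """Aggregate every labeled cell into a feature table (one row per cell)."""
    labels = np.unique(np.asarray(label_image))
    labels = labels[labels > 0]
    records = [
        aggregate_cell(
            fitmaps,
            cubes,
            label_image,
            int(cid),
            donor=donor,
            condition=condition,
            cell_type=(cell_types or {}).get(int(cid), "unknown"),
        )
        for cid in labels
    ]
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        df = pd.DataFrame(columns=FEATURE_COLUMNS)
    return df[FEATURE_COLUMNS]


def apply_qc(table: pd.DataFrame, rules=None) -> pd.DataFrame:
    """Flag rows violating any exclusion rule; returns a copy.

    Each failing row gets ``qc_pass=False`` and a comma-joined list of all
    applicable reason codes.  The operation is idempotent: rules are
    re-evaluated from the measured columns, not from previous flags, and a
    prior "no-valid-pixels" flag is preserved.
    """
    rules = QC_RULES if rules is None else rules
    df = table.copy()
    if df.empty:
        return df
    prior_nvp = df.get("qc_reasons", pd.Series("", index=df.index)).fillna("")
    prior_nvp = prior_nvp.str.contains("no-valid-pixels")
    reasons = [[] for _ in range(len(df))]
    for col, op, thr, code in rules:
        v = df[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = v < thr if op == "lt" else v > thr
        bad |= np.isnan(v)
        for i in np.nonzero(bad)[0]:
            reasons[i].append(code)
    for i, flag in enumerate(prior_nvp.to_numpy()):
        if flag:
            reasons[i].insert(0, "no-valid-pixels")
    df["qc_reasons"] = [",".join(r) for r in reasons]
    df["qc_pass"] = [len(r) == 0 for r in reasons]
    return df


def qc_passed(table: pd.DataFrame) -> pd.DataFrame:
    """Rows of an already-QC'd table that passed every rule."""
    return table[table["qc_pass"]].reset_index(drop=True)


def qc_summary(table: pd.DataFrame) -> dict:
    """Counts of excluded cells per reason code (a cell may count twice)."""
    counts: dict[str, int] = {}
    for rs in table.loc[~table["qc_pass"], "qc_reasons"]:
        for code in filter(None, rs.split(",")):
            counts[code] = counts.get(code, 0) + 1
    return {
        "n_cells": int(len(table)),
        "n_pass": int(table["qc_pass"].sum()),
        "excluded_by_reason": counts,
    }


def gate_cd56(
    table: pd.DataFrame,
    intensity_column: str = "cd56_intensity",
    threshold: float = 100.0,
) -> pd.DataFrame:
    """Split NK cells into CD56 bright / dim by stain intensity.

    Bright means intensity strictly above ``threshold`` (default 100 a.u.,
    chosen to capture roughly the top 10% brightest NK cells).  Returns a
    copy with a ``cd56_bright`` column; the bright fraction is stored in
    ``DataFrame.attrs['cd56_bright_fraction']``.
    """
    if intensity_column not in table.columns:
        raise KeyError(f"missing stain intensity column {intensity_column!r}")
    df = table.copy()
    df["cd56_bright"] = df[intensity_column].to_numpy(dtype=float) > threshold
    df.attrs["cd56_bright_fraction"] = float(df["cd56_bright"].mean())
    return df


def gate_cd69(
    activated_intensities: np.ndarray,
    quiescent_intensities: np.ndarray,
    n_sd: float = 1.5,
) -> tuple[np.ndarray, float, float]:
    """Call CD69-positive cells against the quiescent population.

    The threshold is mean(quiescent) + ``n_sd`` * SD(quiescent) with the
    sample (n-1) standard deviation; a cell is positive iff its intensity is
    strictly above the threshold.  Returns (positive calls for the activated
    cells, positive fraction, threshold).  A zero-variance quiescent
    population collapses the threshold to its mean.
    """
    q = np.asarray(quiescent_intensities, dtype=float)
    a = np.asarray(activated_intensities, dtype=float)
    if q.size < 2:
        raise ValueError("need at least 2 quiescent cells to set the gate")
    sd = float(q.std(ddof=1))
    if sd == 0:
        import warnings

        warnings.warn("zero-variance quiescent population; threshold = mean")
    thr = float(q.mean()) + n_sd * sd
    pos = a > thr
    return pos, float(pos.mean()), thr
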