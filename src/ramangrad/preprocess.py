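"""Spectral preprocessing chain.

Five steps, applied per spectrum in this order: cosmic-ray removal,
Savitzky-Golay smoothing (window 35, order 2), asymmetric-least-squares
(ALS) baseline estimation and subtraction, mean-intensity centering, and
replicate averaging.

Despiking is a modified-z-score detector on the residual against a median
filter (cosmic rays are 1-3 channel positive outliers; genuine Raman bands
are wider and are never repaired), with linear-interpolation repair.

The ALS baseline solves, for ``n_iter`` iterations,

    (W + lam * D'D) z = W y,    W = diag(w),  D = second-difference operator,

then updates w_i = p where y_i > z_i else 1 - p (w starts at 1). The
smoothness penalty ``lam`` defaults to 1e6, the magnitude standard in
chemometrics for channel counts of this order; values many decades smaller
make the penalty negligible so the baseline tracks the signal itself and
subtraction removes everything (``PRINTED_ALS_LAMBDA`` preserves one such
literature value for comparison). The linear system is solved with a banded
factorization, so cost is linear in the channel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import solve_banded
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .dataset import META_COLUMNS, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "BaselineResult",
    "PRINTED_ALS_LAMBDA",
    "remove_cosmic_rays",
    "savgol_smooth",
    "als_baseline",
    "subtract_and_center",
    "average_replicates",
    "preprocess_pipeline",
]

#: A literature-reported ALS smoothness value that is far too small to act as
#: a penalty on count-scale spectra; kept for reference, not used as default.
PRINTED_ALS_LAMBDA = 1e-6


@dataclass
class PreprocessConfig:
    """Parameters of the five-step chain."""

    sg_window: int = 35
    sg_order: int = 2
    als_lambda: float = 1e6
    als_p: float = 0.01
    als_iters: int = 10
    despike_threshold: float = 8.0
    despike_max_width: int = 3
    average_by: tuple | None = None   # e.g. ("zone", "day", "condition"); None = no averaging

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if not 0 < self.als_p < 1:
            raise ValueError("als_p must lie in (0, 1)")
        if self.als_lambda <= 0:
            raise ValueError("als_lambda must be positive")


@dataclass
class BaselineResult:
    """ALS output: the baseline, final asymmetry weights, iterations used."""

    baseline: np.ndarray
    weights: np.ndarray
    n_iter_used: int


# ---------------------------------------------------------------------------
# Cosmic-ray removal
# ---------------------------------------------------------------------------


def _despike_one(y: np.ndarray, threshold: float, max_width: int) -> np.ndarray:
    med = median_filter(y, size=7, mode="nearest")
    r = y - med
    mad = np.median(np.abs(r - np.median(r)))
    sigma = 1.4826 * mad
    if sigma == 0:
        sigma = np.finfo(float).tiny
    flagged = r > threshold * sigma  # cosmic rays are positive
    if flagged.all():
        raise ValueError("every channel flagged as a spike; spectrum unusable")
    if not flagged.any():
        return y
    # prune runs wider than a cosmic-ray can be: those are real bands
    out_flag = flagged.copy()
    idx = np.flatnonzero(flagged)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if run.size > max_width:
            out_flag[run] = False
    if not out_flag.any():
        return y
    good = ~out_flag
    repaired = y.copy()
    repaired[out_flag] = np.interp(
        np.flatnonzero(out_flag), np.flatnonzero(good), y[good]
    )
    return repaired


def remove_cosmic_rays(
    sset: SpectrumSet, threshold: float = 8.0, max_width: int = 3
) -> SpectrumSet:
    """Replace narrow high-amplitude outlier channels by linear interpolation.

    Detection is per spectrum: the residual against a 7-channel median filter
    is scored by a robust (MAD-based) z-score; channels above ``threshold``
    in runs no wider than ``max_width`` are treated as cosmic rays.
    """
    if sset.n_spectra < 1:
        raise ValueError("need at least one spectrum")
    X = np.array([_despike_one(row, threshold, max_width) for row in sset.intensities])
    return sset.with_intensities(X)


# ---------------------------------------------------------------------------
# Smoothing, baseline, centering
# ---------------------------------------------------------------------------


def savgol_smooth(y: np.ndarray, window: int = 35, order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing; boundary windows use a polynomial fit on the
    available samples (no padding artifacts)."""
    y = np.asarray(y, dtype=float)
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if window > y.size:
        raise ValueError("window longer than the spectrum")
    return savgol_filter(y, window, order, mode="interp")


def als_baseline(y: np.ndarray, lam: float = 1e6, p: float = 0.01, n_iter: int = 10) -> BaselineResult:
    """Asymmetric-least-squares baseline (Eilers-style) via a banded solve."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("input must be finite")
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 channels")
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = (lam * (D.T @ D)).todia()
    w = np.ones(n)
    z = y.copy()
    for it in range(n_iter):
        A = penalty.copy()
        A.setdiag(A.diagonal() + w)
        ab = _dia_to_banded(A)
        z = solve_banded((2, 2), ab, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return BaselineResult(baseline=z, weights=w, n_iter_used=n_iter)


def _dia_to_banded(A: sparse.dia_matrix) -> np.ndarray:
    """Pack a pentadiagonal sparse matrix into LAPACK banded storage."""
    n = A.shape[0]
    ab = np.zeros((5, n))
    for offset in (-2, -1, 0, 1, 2):
        diag = A.diagonal(offset)
        row = 2 - offset
        if offset >= 0:
            ab[row, offset:] = diag
        else:
            ab[row, : n + offset] = diag
    return ab


def subtract_and_center(y: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Background subtraction followed by mean-intensity centering."""
    y = np.asarray(y, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if y.shape != baseline.shape:
        raise ValueError("spectrum and baseline must be aligned")
    r = y - baseline
    return r - r.mean()


# ---------------------------------------------------------------------------
# Averaging and the full chain
# ---------------------------------------------------------------------------


def average_replicates(sset: SpectrumSet, group_keys: Sequence[str]) -> SpectrumSet:
    """One mean spectrum per metadata group; group sizes recorded in ``n_averaged``."""
    group_keys = list(group_keys)
    for k in group_keys:
        if k not in sset.meta.columns:
            raise KeyError(f"group key {k!r} not in metadata")
    df = sset.meta.copy()
    df["_row"] = np.arange(len(df))
    rows, metas = [], []
    for keys, block in df.groupby(group_keys, sort=True, dropna=False):
        idx = block["_row"].to_numpy()
        rows.append(sset.intensities[idx].mean(axis=0))
        rec = dict(sset.meta.iloc[idx[0]][META_COLUMNS])
        if not isinstance(keys, tuple):
            keys = (keys,)
        rec.update(dict(zip(group_keys, keys)))
        rec["n_averaged"] = len(idx)
        metas.append(rec)
    meta = pd.DataFrame(metas)
    return SpectrumSet(sset.axis, np.vstack(rows), meta)


def preprocess_pipeline(
    sset: SpectrumSet, config: PreprocessConfig | None = None
) -> tuple[SpectrumSet, dict]:
    """Run the five-step chain; returns the processed set and a run log.

    The log echoes every parameter actually used, in order, so a processed
    dataset is fully reproducible from its sidecar.
    """
    if config is None:
        config = PreprocessConfig()
    if sset.n_spectra == 0:
        raise ValueError("empty SpectrumSet")
    log = {"steps": [], "parameters": asdict(config)}

    out = remove_cosmic_rays(sset, config.despike_threshold, config.despike_max_width)
    log["steps"].append({"step": "remove_cosmic_rays",
                         "threshold": config.despike_threshold,
                         "max_width": config.despike_max_width})

    X = np.array([savgol_smooth(r, config.sg_window, config.sg_order) for r in out.intensities])
    out = out.with_intensities(X)
    log["steps"].append({"step": "savgol_smooth",
                         "window": config.sg_window, "order": config.sg_order})

    rows = []
    for r in out.intensities:
        bl = als_baseline(r, config.als_lambda, config.als_p, config.als_iters)
        rows.append(subtract_and_center(r, bl.baseline))
    out = out.with_intensities(np.array(rows))
    log["steps"].append({"step": "als_baseline_subtract_center",
                         "lam": config.als_lambda, "p": config.als_p,
                         "n_iter": config.als_iters})

    if config.average_by:
        out = average_replicates(out, config.average_by)
        log["steps"].append({"step": "average_replicates",
                             "group_keys": list(config.average_by)})
    else:
        log["steps"].append({"step": "average_replicates", "skipped": True})
    return out, log
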