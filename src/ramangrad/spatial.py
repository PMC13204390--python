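"""Band-intensity extraction and spatial analyses along the chamber.

Covers the x-axis analyses (band gradient maps, erfc diffusion-profile
fitting of the adenine validation) and the z-axis focal-plane selection from
a vertical scan between the two glass windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .chemometrics import pca
from .dataset import SpectrumSet
from .synthdata import closed_form_diffusion

__all__ = [
    "BandDefinition",
    "GradientMap",
    "DiffusionFit",
    "FocusSelection",
    "BAND_REGISTRY",
    "resolve_band",
    "band_intensity",
    "detect_peak",
    "build_gradient_map",
    "zscan_select_focus",
    "fit_diffusion_profile",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named integration window: mean intensity over center +/- half_window."""

    name: str
    center: float
    half_window: float = 5.0


#: Canonical band centers; nearby literature variants (685, 1041) are aliases
#: of the same bands — the +/-5 cm^-1 windowed mean makes the 1-5 cm^-1
#: discrepancy immaterial.
BAND_REGISTRY: Dict[str, BandDefinition] = {
    "glucose": BandDefinition("glucose", 1125.0),
    "lactate": BandDefinition("lactate", 853.0),
    "stress": BandDefinition("stress", 680.0),
    "adenine": BandDefinition("adenine", 725.0),
    "ph_hepes": BandDefinition("ph_hepes", 1040.0),
}
_ALIASES = {"685": "stress", "680": "stress", "1040": "ph_hepes", "1041": "ph_hepes",
            "853": "lactate", "1125": "glucose", "725": "adenine"}


def resolve_band(name_or_center: str | float) -> BandDefinition:
    """Look up a band by name, alias, or numeric center."""
    key = str(name_or_center)
    if key in BAND_REGISTRY:
        return BAND_REGISTRY[key]
    if key in _ALIASES:
        return BAND_REGISTRY[_ALIASES[key]]
    try:
        center = float(name_or_center)
    except (TypeError, ValueError):
        raise KeyError(f"unknown band {name_or_center!r}") from None
    return BandDefinition(f"band_{center:g}", center)


def band_intensity(axis: np.ndarray, y: np.ndarray, band: BandDefinition) -> float:
    """Mean intensity over the band window (linear in the spectrum)."""
    axis = np.asarray(axis, dtype=float)
    lo, hi = band.center - band.half_window, band.center + band.half_window
    if lo < axis[0] or hi > axis[-1]:
        raise ValueError(f"band window [{lo}, {hi}] outside the axis")
    m = (axis >= lo) & (axis <= hi)
    return float(np.mean(np.asarray(y, dtype=float)[m]))


def detect_peak(axis: np.ndarray, y: np.ndarray, search_window: tuple[float, float]) -> float:
    """Parabolically interpolated argmax within a wavenumber window (cm^-1).

    A maximum on the window boundary (monotone signal) is returned as-is with
    a flat-peak warning.
    """
    axis = np.asarray(axis, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = search_window
    if lo < axis[0] or hi > axis[-1] or lo >= hi:
        raise ValueError("search window must lie within the axis")
    m = np.flatnonzero((axis >= lo) & (axis <= hi))
    yi = y[m]
    j = int(np.argmax(yi))
    if j == 0 or j == yi.size - 1:
        warnings.warn("peak at window boundary; flat or monotone signal", stacklevel=2)
        return float(axis[m[j]])
    y0, y1, y2 = yi[j - 1], yi[j], yi[j + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        warnings.warn("flat peak; parabolic refinement undefined", stacklevel=2)
        return float(axis[m[j]])
    delta = 0.5 * (y0 - y2) / denom
    step = axis[1] - axis[0]
    return float(axis[m[j]] + delta * step)


# ---------------------------------------------------------------------------
# Gradient mapping
# ---------------------------------------------------------------------------


@dataclass
class GradientMap:
    """Per-day band intensities along x: one (n_days x n_positions) table per band."""

    x_positions: np.ndarray
    days: np.ndarray
    values: Dict[str, np.ndarray]       # band name -> (n_days, n_x)

    def to_frame(self, band: str) -> pd.DataFrame:
        return pd.DataFrame(self.values[band],
                            index=pd.Index(self.days, name="day"),
                            columns=pd.Index(self.x_positions, name="x_mm"))


def build_gradient_map(
    sset: SpectrumSet,
    bands: Sequence[BandDefinition | str | float],
    group_by_day: bool = True,
) -> GradientMap:
    """Replicate-averaged band intensity at each x position (per day).

    Positions come from the ``x_mm`` metadata column and are sorted
    ascending; at least two distinct positions are required.
    """
    bands = [b if isinstance(b, BandDefinition) else resolve_band(b) for b in bands]
    x = sset.meta["x_mm"].to_numpy(dtype=float)
    positions = np.unique(x)
    if positions.size < 2:
        raise ValueError("need at least 2 distinct x positions")
    days = (np.unique(sset.meta["day"].to_numpy()) if group_by_day else np.array([0]))
    values = {}
    for band in bands:
        table = np.full((days.size, positions.size), np.nan)
        for i, day in enumerate(days):
            sel_day = np.ones(len(sset.meta), dtype=bool)
            if group_by_day:
                sel_day = sset.meta["day"].to_numpy() == day
            for j, pos in enumerate(positions):
                sel = sel_day & np.isclose(x, pos)
                if sel.any():
                    vals = [band_intensity(sset.axis, row, band)
                            for row in sset.intensities[sel]]
                    table[i, j] = float(np.mean(vals))
        values[band.name] = table
    return GradientMap(x_positions=positions, days=days, values=values)


# ---------------------------------------------------------------------------
# z-scan focal-plane selection
# ---------------------------------------------------------------------------


@dataclass
class FocusSelection:
    interval: tuple[float, float]       # contiguous glass-free z range, mm
    recommended_z: float
    scores: np.ndarray                  # PCA scores of the scan
    inlier: np.ndarray                  # boolean per focal height


class FocusSelectionError(RuntimeError):
    """No contiguous central cluster of glass-free spectra exists."""


def zscan_select_focus(
    zscan: SpectrumSet,
    clearance_mm: float = 0.3,
    n_components: int = 2,
) -> FocusSelection:
    """Pick the focal height minimizing glass interference from a z-scan.

    PCA is run on the scan; spectra whose score-space distance to the
    centroid of the middle third stays within a robust spread estimate
    (median + 3 * 1.4826 * MAD of the middle-third distances, with a small
    numerical floor) are inliers. The recommended focal height is the lowest
    inlier z at or above ``clearance_mm`` — the interval point closest to the
    cell layer while clearing the bottom window.
    """
    z = zscan.meta["z_mm"].to_numpy(dtype=float)
    if z.size < 5:
        raise ValueError("need at least 5 focal heights")
    order = np.argsort(z)
    z = z[order]
    X = zscan.intensities[order]
    k = min(n_components, X.shape[0] - 1)
    res = pca(X, k)
    scores = res.scores
    n = z.size
    mid = slice(n // 3, n - n // 3)
    centroid = scores[mid].mean(axis=0)
    d = np.linalg.norm(scores - centroid, axis=1)
    d_mid = d[mid]
    sigma = 1.4826 * np.median(np.abs(d_mid - np.median(d_mid)))
    thresh = np.median(d_mid) + 3.0 * max(sigma, 1e-9 * (d.max() + 1e-300))
    inlier = d <= thresh
    # contiguous run containing the center of the scan
    center_idx = n // 2
    if not inlier[center_idx]:
        raise FocusSelectionError("no contiguous central cluster in the z-scan")
    lo = center_idx
    while lo > 0 and inlier[lo - 1]:
        lo -= 1
    hi = center_idx
    while hi < n - 1 and inlier[hi + 1]:
        hi += 1
    interval = (float(z[lo]), float(z[hi]))
    candidates = z[lo : hi + 1]
    above = candidates[candidates >= clearance_mm - 1e-12]
    if above.size == 0:
        raise FocusSelectionError(
            f"no glass-free focal height clears {clearance_mm} mm above the bottom window"
        )
    return FocusSelection(interval=interval, recommended_z=float(above[0]),
                          scores=scores, inlier=inlier)


# ---------------------------------------------------------------------------
# Diffusion-profile fitting
# ---------------------------------------------------------------------------


@dataclass
class DiffusionFit:
    D_hat: float                        # mm^2/h
    C0_hat: float                       # intensity units
    rss: float


def fit_diffusion_profile(
    x: np.ndarray,
    intensities: np.ndarray,
    t: float,
    d_bounds: tuple[float, float] = (1e-3, 10.0),
    n_starts: int = 8,
) -> DiffusionFit:
    """Fit I(x) = C0 * erfc(x / (2 sqrt(D t))) by nonlinear least squares.

    Multi-start over log-spaced D initial values inside ``d_bounds`` (the
    small-molecule aqueous range at this scale); the best residual wins.
    """
    x = np.asarray(x, dtype=float)
    I = np.asarray(intensities, dtype=float)
    if x.size != I.size:
        raise ValueError("x and intensities must be aligned")
    if x.size < 4:
        raise ValueError("need at least 4 positions")
    if t <= 0:
        raise ValueError("t must be positive")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(I))):
        raise ValueError("inputs must be finite")
    if np.ptp(I) == 0:
        raise ValueError("intensities are constant; D is unidentifiable")

    def model(xv, c0, d):
        return closed_form_diffusion(xv, t, d, c0)

    best = None
    c0_init = float(max(I.max(), 1e-12))
    for d0 in np.geomspace(d_bounds[0], d_bounds[1], n_starts):
        try:
            popt, _ = curve_fit(
                model, x, I, p0=[c0_init, d0],
                bounds=([0.0, d_bounds[0]], [np.inf, d_bounds[1]]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((model(x, *popt) - I) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError("diffusion-profile fit failed from every start")
    rss, (c0, d) = best
    return DiffusionFit(D_hat=float(d), C0_hat=float(c0), rss=rss)
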