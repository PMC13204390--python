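"""Spectral containers and plain-text I/O.

A :class:`Spectrum` is one intensity vector on a wavenumber axis with
acquisition metadata; a :class:`SpectrumSet` is a row-major stack of spectra
sharing one axis, with a :class:`pandas.DataFrame` of per-spectrum metadata
aligned to the rows. These two containers are the currency of every stage of
the pipeline (simulation, preprocessing, chemometrics, mapping).

Two CSV dialects are supported for interchange:

``long``
    One row per (spectrum, channel): columns ``spectrum_id``,
    ``wavenumber_cm1``, ``intensity`` plus the metadata columns.
``wide``
    One row per spectrum, one column per wavenumber, plus a sidecar
    ``*.meta.csv`` holding the metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Metadata columns carried by every SpectrumSet, in canonical order.
META_COLUMNS = ["zone", "day", "replicate", "x_mm", "z_mm", "condition", "cell_line"]

#: Zone partition along the chamber (mm from the reservoir face).
ZONE_BOUNDS = {"z1": (0.0, 5.0), "z2": (5.0, 10.0), "z3": (10.0, 15.0)}

#: Chamber length, mm.
CHAMBER_LENGTH_MM = 15.0

#: Chamber depth between the two glass windows, mm.
CHAMBER_DEPTH_MM = 1.5


def zone_center(zone: str) -> float:
    """Midpoint x-position of a named zone, mm."""
    lo, hi = ZONE_BOUNDS[zone]
    return 0.5 * (lo + hi)


def zone_of(x_mm: float) -> str:
    """Zone label containing position ``x_mm`` (z3 closed at 15 mm)."""
    for name, (lo, hi) in ZONE_BOUNDS.items():
        if lo <= x_mm < hi:
            return name
    if np.isclose(x_mm, CHAMBER_LENGTH_MM):
        return "z3"
    raise ValueError(f"x = {x_mm} mm outside the 0-{CHAMBER_LENGTH_MM} mm chamber")


def make_axis(start: float = 600.0, stop: float = 1200.0, step: float = 1.0) -> np.ndarray:
    """Uniform wavenumber grid in cm^-1, endpoints inclusive."""
    n = int(round((stop - start) / step)) + 1
    axis = start + step * np.arange(n)
    validate_axis(axis)
    return axis


def validate_axis(values: np.ndarray) -> None:
    """Enforce a strictly increasing, uniformly spaced axis of length >= 2."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("wavenumber axis must be 1-D with at least 2 channels")
    d = np.diff(values)
    if np.any(d <= 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-8, atol=1e-8):
        raise ValueError("wavenumber axis must be uniformly spaced")


@dataclass
class AcquisitionMeta:
    """Where/when/how one spectrum was acquired."""

    zone: str = "none"
    day: int = 0
    replicate: int = 1
    x_mm: float = 0.0
    z_mm: float = 0.4
    condition: str = "cells"
    cell_line: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.z_mm <= CHAMBER_DEPTH_MM:
            raise ValueError(f"focal height z = {self.z_mm} mm outside [0, {CHAMBER_DEPTH_MM}]")
        if self.zone not in ("none", *ZONE_BOUNDS):
            raise ValueError(f"unknown zone {self.zone!r}")
        if self.zone in ZONE_BOUNDS:
            lo, hi = ZONE_BOUNDS[self.zone]
            if not (lo <= self.x_mm <= hi):
                raise ValueError(
                    f"x = {self.x_mm} mm inconsistent with zone {self.zone} = [{lo}, {hi}] mm"
                )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in META_COLUMNS}


@dataclass
class Spectrum:
    """A single Raman spectrum: intensities on a wavenumber axis."""

    axis: np.ndarray
    intensity: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        validate_axis(self.axis)
        if self.intensity.shape != self.axis.shape:
            raise ValueError("intensity length must equal axis length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


class SpectrumSet:
    """n_spectra x n_channels intensity matrix with aligned metadata.

    Parameters
    ----------
    axis
        Shared wavenumber axis (cm^-1).
    intensities
        Row-major matrix, one spectrum per row.
    meta
        DataFrame with one row per spectrum; missing canonical columns are
        filled with defaults.
    """

    def __init__(self, axis: np.ndarray, intensities: np.ndarray, meta: pd.DataFrame | None = None):
        self.axis = np.asarray(axis, dtype=float)
        validate_axis(self.axis)
        X = np.asarray(intensities, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.axis.size:
            raise ValueError("intensity matrix width must equal axis length")
        if not np.all(np.isfinite(X)):
            raise ValueError("intensities must be finite")
        self.intensities = X
        if meta is None:
            meta = pd.DataFrame(index=range(X.shape[0]))
        if len(meta) != X.shape[0]:
            raise ValueError("metadata row count must equal spectrum count")
        meta = meta.reset_index(drop=True).copy()
        defaults = AcquisitionMeta()
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = getattr(defaults, col)
        self.meta = meta

    # -- basic protocol ----------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def __len__(self) -> int:
        return self.n_spectra

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        meta = AcquisitionMeta(**{k: row[k] for k in META_COLUMNS})
        return Spectrum(self.axis, self.intensities[i], meta)

    def select(self, mask) -> "SpectrumSet":
        """Subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectrumSet(self.axis, self.intensities[idx], self.meta.iloc[idx])

    def with_intensities(self, X: np.ndarray) -> "SpectrumSet":
        """Same axis and metadata, new intensity matrix."""
        return SpectrumSet(self.axis, X, self.meta)

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise ValueError("cannot build a SpectrumSet from zero spectra")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if not np.array_equal(s.axis, axis):
                raise ValueError("all spectra must share one wavenumber axis")
        X = np.vstack([s.intensity for s in spectra])
        meta = pd.DataFrame([s.meta.as_dict() for s in spectra])
        return cls(axis, X, meta)

    @classmethod
    def concat(cls, sets: Iterable["SpectrumSet"]) -> "SpectrumSet":
        sets = list(sets)
        axis = sets[0].axis
        for s in sets[1:]:
            if not np.array_equal(s.axis, axis):
                raise ValueError("all sets must share one wavenumber axis")
        X = np.vstack([s.intensities for s in sets])
        meta = pd.concat([s.meta for s in sets], ignore_index=True)
        return cls(axis, X, meta)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_spectrumset(sset: SpectrumSet, path: str | Path, dialect: str = "long") -> Path:
    """Write a SpectrumSet to CSV.

    ``long`` writes one file; ``wide`` writes the matrix to ``path`` and the
    metadata to ``<stem>.meta.csv`` alongside it. Returns the main path.
    """
    path = Path(path)
    if dialect == "long":
        frames = []
        for i in range(sset.n_spectra):
            df = pd.DataFrame(
                {
                    "spectrum_id": i,
                    "wavenumber_cm1": sset.axis,
                    "intensity": sset.intensities[i],
                }
            )
            for col in META_COLUMNS:
                df[col] = sset.meta.iloc[i][col]
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif dialect == "wide":
        wide = pd.DataFrame(sset.intensities, columns=[_FLOAT_FMT % w for w in sset.axis])
        wide.insert(0, "spectrum_id", range(sset.n_spectra))
        wide.to_csv(path, index=False, float_format=_FLOAT_FMT)
        meta = sset.meta[META_COLUMNS].copy()
        meta.insert(0, "spectrum_id", range(sset.n_spectra))
        meta.to_csv(_meta_path(path), index=False, float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (use 'long' or 'wide')")
    return path


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.csv")


def read_spectrumset(path: str | Path, dialect: str = "long") -> SpectrumSet:
    """Read a SpectrumSet written by :func:`write_spectrumset`.

    Raises ``ValueError`` with the offending row index on malformed
    (non-numeric) intensity values.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path)
        bad = pd.to_numeric(df["intensity"], errors="coerce").isna() & df["intensity"].notna()
        if bad.any() or df["intensity"].isna().any():
            row = int(np.flatnonzero(bad | df["intensity"].isna())[0])
            raise ValueError(f"non-numeric intensity at data row {row}")
        ids = df["spectrum_id"].unique()
        first = df[df["spectrum_id"] == ids[0]]
        axis = first["wavenumber_cm1"].to_numpy(dtype=float)
        X = np.empty((len(ids), axis.size))
        meta_rows = []
        for k, sid in enumerate(ids):
            block = df[df["spectrum_id"] == sid]
            if not np.allclose(block["wavenumber_cm1"].to_numpy(dtype=float), axis):
                raise ValueError("spectra in a long CSV must share one axis")
            X[k] = pd.to_numeric(block["intensity"]).to_numpy()
            meta_rows.append({c: block.iloc[0][c] for c in META_COLUMNS})
        return SpectrumSet(axis, X, pd.DataFrame(meta_rows))
    if dialect == "wide":
        wide = pd.read_csv(path)
        axis = np.array([float(c) for c in wide.columns if c != "spectrum_id"])
        data = wide.drop(columns=["spectrum_id"])
        coerced = data.apply(pd.to_numeric, errors="coerce")
        if coerced.isna().any().any():
            row = int(np.flatnonzero(coerced.isna().any(axis=1))[0])
            raise ValueError(f"non-numeric intensity at data row {row}")
        meta = pd.read_csv(_meta_path(path)).drop(columns=["spectrum_id"])
        return SpectrumSet(axis, coerced.to_numpy(dtype=float), meta)
    raise ValueError(f"unknown dialect {dialect!r} (use 'long' or 'wide')")
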