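"""Forward model of the diffusion-fed microreactor experiment.

The chamber is a 15 mm channel fed from one end by a nutrient reservoir.
Cells distributed along the channel consume glucose (Michaelis-Menten),
excrete lactate (with protons that acidify the HEPES-buffered medium) and,
under nutrient or pH stress, release a purine-like stress marker detected at
680 cm^-1. Transport is one-dimensional passive diffusion: a Dirichlet
boundary at the reservoir face (x = 0, concentrations held at reservoir
values) and a zero-flux wall at x = 15 mm.

The module provides

* a library of analyte band models (glucose 1125, lactate 853, adenine 725,
  stress marker 680, the pH-sensitive HEPES pair at 1040/1048 cm^-1, and
  fixed medium bands including 980 cm^-1),
* an explicit finite-volume reaction-diffusion solver producing a
  :class:`FieldState` (concentration and pH profiles over time),
* the closed-form semi-infinite diffusion profile ``C0*erfc(x/(2*sqrt(D t)))``
  used as an independent check on the solver,
* a spectral renderer (peaks + fluorescence baseline + focal-height-dependent
  glass bands + Gaussian noise + cosmic-ray spikes), and
* generators reproducing the acquisition designs: the 3-zone x 4-day x
  15-replicate study, the 0-1.5 mm z-scan at 100 um steps, the adenine
  diffusion validation, the pH 4-10 HEPES series, and serial-dilution
  calibration series.

Every generator is deterministic under a given integer seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .dataset import (
    CHAMBER_DEPTH_MM,
    CHAMBER_LENGTH_MM,
    AcquisitionMeta,
    Spectrum,
    SpectrumSet,
    make_axis,
    zone_center,
    zone_of,
)

__all__ = [
    "PeakComponent",
    "AnalyteModel",
    "FieldState",
    "ReactionDiffusionParams",
    "NoiseSettings",
    "ExperimentDesign",
    "build_analyte_library",
    "closed_form_diffusion",
    "simulate_reaction_diffusion",
    "render_spectrum",
    "generate_experiment",
    "generate_ph_series",
    "generate_dilution_series",
    "generate_zscan",
    "generate_chamber_map",
    "generate_adenine_diffusion",
    "stage_rng",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a per-stage random generator from one global seed.

    The sub-seed mixes the seed with a CRC32 of the stage name so stages can
    be rerun in isolation while staying deterministic.
    """
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(stage.encode()) % 2**31])


# ---------------------------------------------------------------------------
# Band models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakComponent:
    """One spectral band: center (cm^-1), FWHM (cm^-1), shape, amplitude.

    ``molar_amplitude`` is the peak height in counts contributed per unit
    concentration (mM for metabolites; dimensionless "1x medium" for the
    fixed medium components).
    """

    center: float
    fwhm: float
    shape: str = "lorentzian"
    molar_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.molar_amplitude < 0:
            raise ValueError("molar_amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-concentration band profile on ``axis`` (peak height = molar_amplitude)."""
        d = axis - self.center
        if self.shape == "lorentzian":
            g = self.fwhm / 2.0
            return self.molar_amplitude * g * g / (d * d + g * g)
        return self.molar_amplitude * np.exp(-4.0 * np.log(2.0) * d * d / self.fwhm**2)


@dataclass(frozen=True)
class AnalyteModel:
    """Peak-component description of one chemical species.

    pH-sensitive analytes (HEPES) carry two component lists, one per
    protonation state, mixed by Henderson-Hasselbalch at the local pH.
    ``titration_pkas``, if non-empty, scales the whole response by the mean
    protonated->deprotonated fraction over that pKa grid — used for the
    aggregate titration behaviour of a multi-component medium.
    """

    name: str
    components: tuple = ()
    ph_sensitive: bool = False
    pka: float | None = None
    acid_components: tuple = ()
    base_components: tuple = ()
    titration_pkas: tuple = ()

    def __post_init__(self) -> None:
        if self.ph_sensitive and (not self.acid_components or not self.base_components):
            raise ValueError("pH-sensitive analyte needs acid and base component lists")
        if self.ph_sensitive and self.pka is None:
            raise ValueError("pH-sensitive analyte needs a pKa")

    def base_fraction(self, ph: float) -> float:
        """Deprotonated fraction at ``ph`` (Henderson-Hasselbalch)."""
        if self.pka is None:
            raise ValueError(f"{self.name} has no pKa")
        return 1.0 / (1.0 + 10.0 ** (self.pka - ph))

    def response(self, axis: np.ndarray, conc: float, ph: float | None = None) -> np.ndarray:
        """Spectral contribution of this analyte at concentration ``conc``."""
        y = np.zeros_like(axis, dtype=float)
        if conc == 0:
            return y
        for c in self.components:
            y += c.profile(axis)
        if self.ph_sensitive:
            if ph is None:
                raise ValueError(f"{self.name} requires a pH to evaluate")
            f = self.base_fraction(ph)
            for c in self.acid_components:
                y += (1.0 - f) * c.profile(axis)
            for c in self.base_components:
                y += f * c.profile(axis)
        if self.titration_pkas:
            if ph is None:
                raise ValueError(f"{self.name} requires a pH to evaluate")
            fracs = [1.0 / (1.0 + 10.0 ** (pk - ph)) for pk in self.titration_pkas]
            y *= float(np.mean(fracs))
        return conc * y

    def principal_center(self) -> float:
        """Center of the strongest fixed component (acid component for HEPES)."""
        comps = self.components or self.acid_components
        return max(comps, key=lambda c: c.molar_amplitude).center


#: HEPES pKa at 37 C.
HEPES_PKA = 7.5

#: Standard HEPES concentration in the buffered medium, mM.
HEPES_MEDIUM_MM = 25.0


def build_analyte_library() -> Dict[str, AnalyteModel]:
    """Band models for every species the forward model renders.

    Metabolite bands are sharp Lorentzians (FWHM 8-12 cm^-1) at their
    field-standard positions; amplitudes are counts per mM chosen so that
    physiological concentrations sit well above the default noise floor.
    """
    L = "lorentzian"
    lib = [
        AnalyteModel(
            "glucose",
            components=(
                PeakComponent(1125.0, 10.0, L, 1.2),
                PeakComponent(1065.0, 12.0, L, 0.45),
            ),
        ),
        AnalyteModel(
            "lactate",
            components=(
                PeakComponent(853.0, 10.0, L, 1.5),
                PeakComponent(930.0, 12.0, L, 0.5),
            ),
        ),
        AnalyteModel("stress_marker", components=(PeakComponent(680.0, 10.0, L, 6.0),)),
        AnalyteModel("adenine", components=(PeakComponent(725.0, 8.0, L, 30.0),)),
        AnalyteModel(
            "hepes",
            ph_sensitive=True,
            pka=HEPES_PKA,
            acid_components=(PeakComponent(1040.0, 11.0, L, 0.8),),
            base_components=(PeakComponent(1048.0, 11.0, L, 1.1),),
        ),
        AnalyteModel(
            "medium_background",
            components=(
                PeakComponent(980.0, 12.0, L, 15.0),
                PeakComponent(1003.0, 9.0, L, 8.0),
            ),
        ),
        # Aggregate titration of the many weak acids/bases in a complex
        # medium: response quasi-linear in pH over a wide range.
        AnalyteModel(
            "medium_titratable",
            components=(PeakComponent(895.0, 14.0, L, 20.0),),
            titration_pkas=tuple(np.arange(3.5, 10.51, 0.5)),
        ),
    ]
    return {m.name: m for m in lib}


#: Glass window marker bands — two manufacturers, two distinct signatures.
GLASS_BOTTOM = (
    PeakComponent(1090.0, 45.0, "gaussian", 1.0),
    PeakComponent(790.0, 40.0, "gaussian", 0.7),
)
GLASS_TOP = (
    PeakComponent(1060.0, 45.0, "gaussian", 1.0),
    PeakComponent(640.0, 40.0, "gaussian", 0.7),
)


# ---------------------------------------------------------------------------
# Reaction-diffusion field
# ---------------------------------------------------------------------------


@dataclass
class FieldState:
    """Time-resolved 1-D concentration and pH profiles along the chamber.

    ``x_mm`` are cell-center positions (0 = reservoir face), ``t_h`` output
    times in hours, ``conc`` maps analyte name -> (n_t, n_x) array in mM,
    ``ph`` is (n_t, n_x) in pH units.
    """

    x_mm: np.ndarray
    t_h: np.ndarray
    conc: Dict[str, np.ndarray]
    ph: np.ndarray

    def __post_init__(self) -> None:
        for name, c in self.conc.items():
            if np.any(c < -1e-12):
                raise ValueError(f"negative concentration in {name}")
        if np.any(self.ph < 0) or np.any(self.ph > 14):
            raise ValueError("pH outside [0, 14]")

    def at(self, x: float, t: float) -> tuple[Dict[str, float], float]:
        """Bilinear lookup of (concentrations, pH) at position ``x`` and time ``t``."""
        if not (self.x_mm[0] - 1e-9 <= x <= self.x_mm[-1] + 1e-9):
            # allow the half-cell margins of the finite-volume grid
            if not (0.0 <= x <= CHAMBER_LENGTH_MM):
                raise ValueError(f"x = {x} mm outside the field grid")
        if not (self.t_h[0] - 1e-9 <= t <= self.t_h[-1] + 1e-9):
            raise ValueError(f"t = {t} h outside the field grid [{self.t_h[0]}, {self.t_h[-1]}]")
        ti = np.clip(np.searchsorted(self.t_h, t), 1, len(self.t_h) - 1)
        t0, t1 = self.t_h[ti - 1], self.t_h[ti]
        w = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        conc = {}
        for name, c in self.conc.items():
            prof = (1 - w) * c[ti - 1] + w * c[ti]
            conc[name] = float(np.interp(x, self.x_mm, prof))
        ph_prof = (1 - w) * self.ph[ti - 1] + w * self.ph[ti]
        return conc, float(np.interp(x, self.x_mm, ph_prof))


@dataclass
class ReactionDiffusionParams:
    """Rates, transport coefficients and boundary settings of the simulator.

    Diffusion coefficients are mm^2/h (0.36 mm^2/h = 1e-10 m^2/s; small
    aqueous metabolites sit in the 1e-10 to 1e-9 m^2/s decade).
    """

    n_cells: int = 60                       # finite-volume cells over 15 mm
    diffusion_mm2_h: Dict[str, float] = field(
        default_factory=lambda: {
            "glucose": 2.4,                 # ~6.7e-10 m^2/s
            "lactate": 2.0,                 # ~5.6e-10 m^2/s
            "stress_marker": 2.5,
            "adenine": 2.3,                 # ~6.4e-10 m^2/s
        }
    )
    reservoir_mM: Dict[str, float] = field(
        default_factory=lambda: {"glucose": 25.0, "lactate": 0.0, "stress_marker": 0.0}
    )
    initial_mM: Dict[str, float] = field(
        default_factory=lambda: {"glucose": 25.0, "lactate": 0.0, "stress_marker": 0.0}
    )
    left_boundary: str = "dirichlet"        # "dirichlet" (reservoir) or "zero_flux"
    reservoir_volume_ratio: float | None = 2.0  # reservoir/chamber volume; None = infinite well
    cell_density: float = 1.0               # relative areal density (0 = control)
    vmax_glucose_mM_h: float = 0.45         # max uptake at unit density
    km_glucose_mM: float = 1.0
    lactate_yield: float = 2.0              # lactate per glucose (glycolysis)
    protons_per_lactate: float = 1.0
    buffer_capacity_mM_per_ph: float = 30.0 # HEPES-dominated buffering
    ph_initial: float = 7.4
    stress_release_mM_h: float = 0.05
    stress_glucose_threshold_mM: float = 5.0
    stress_ph_threshold: float = 6.8
    dt_h: float | None = None               # None -> auto at 0.45*dx^2/Dmax
    output_dt_h: float = 1.0

    def __post_init__(self) -> None:
        for name, d in self.diffusion_mm2_h.items():
            if d < 0:
                raise ValueError(f"negative diffusion coefficient for {name}")
        for v in (self.vmax_glucose_mM_h, self.km_glucose_mM, self.lactate_yield,
                  self.stress_release_mM_h, self.cell_density):
            if v < 0:
                raise ValueError("rates and densities must be non-negative")
        if self.left_boundary not in ("dirichlet", "zero_flux"):
            raise ValueError("left_boundary must be 'dirichlet' or 'zero_flux'")


def closed_form_diffusion(x, t: float, D: float, C0: float):
    """Semi-infinite constant-source diffusion profile C0*erfc(x/(2*sqrt(D t))).

    ``x`` in mm, ``t`` in hours, ``D`` in mm^2/h. Valid while the diffusion
    front is far from the distal wall.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if D <= 0:
        raise ValueError("D must be positive")
    x = np.asarray(x, dtype=float)
    out = C0 * erfc(x / (2.0 * np.sqrt(D * t)))
    return float(out) if out.ndim == 0 else out


def simulate_reaction_diffusion(
    params: ReactionDiffusionParams | None = None, duration_h: float = 96.0
) -> FieldState:
    """Explicit finite-volume solution of the 1-D reaction-diffusion system.

    Cell-centered grid (x_i = (i + 1/2) dx); interior fluxes
    F = D (C_{i+1} - C_i)/dx; the reservoir acts through a half-cell flux at
    the left face (a finite well-mixed compartment whose concentrations
    evolve by mass balance when ``reservoir_volume_ratio`` is set, or an
    infinite constant source when it is None), zero flux at the right face.
    The time step must
    satisfy the FTCS stability bound D dt/dx^2 <= 1/2 for every analyte; an
    auto-chosen step uses 0.45. With ``zero_flux`` on both faces and no
    reactions the scheme conserves mass to machine precision.
    """
    if params is None:
        params = ReactionDiffusionParams()
    dx = CHAMBER_LENGTH_MM / params.n_cells
    x = (np.arange(params.n_cells) + 0.5) * dx
    names = list(params.initial_mM)
    D = {n: params.diffusion_mm2_h.get(n, 0.0) for n in names}
    dmax = max(D.values()) if D else 0.0
    if params.dt_h is None:
        dt = 0.45 * dx * dx / dmax if dmax > 0 else params.output_dt_h
        dt = min(dt, params.output_dt_h)
    else:
        dt = params.dt_h
        if dmax > 0 and dmax * dt / dx**2 > 0.5 + 1e-12:
            raise ValueError(
                f"explicit scheme unstable: max(D)*dt/dx^2 = {dmax * dt / dx**2:.3f} > 0.5; "
                "reduce dt_h or coarsen the grid"
            )

    # scalar initial values fill the chamber uniformly; arrays give a profile
    C = {
        n: np.broadcast_to(np.asarray(params.initial_mM[n], dtype=float), (params.n_cells,)).copy()
        for n in names
    }
    res_conc = dict(params.reservoir_mM)
    res_len = (
        None
        if params.reservoir_volume_ratio is None
        else params.reservoir_volume_ratio * CHAMBER_LENGTH_MM
    )
    out_times = np.arange(0.0, duration_h + 1e-9, params.output_dt_h)
    frames = {n: [C[n].copy()] for n in names}

    def ph_from_lactate(lac: np.ndarray) -> np.ndarray:
        drop = params.protons_per_lactate * lac / params.buffer_capacity_mM_per_ph
        return np.clip(params.ph_initial - drop, 0.0, 14.0)

    ph_frames = [ph_from_lactate(C.get("lactate", np.zeros(params.n_cells)))]

    t = 0.0
    next_out = 1
    rho = params.cell_density
    while t < duration_h - 1e-9:
        step = min(dt, duration_h - t, out_times[min(next_out, len(out_times) - 1)] - t)
        if step <= 0:
            step = dt
        # transport
        for n in names:
            d = D[n]
            if d == 0:
                continue
            c = C[n]
            flux = np.zeros(params.n_cells + 1)  # flux[i] across face left of cell i
            flux[1:-1] = d * (c[1:] - c[:-1]) / dx
            if params.left_boundary == "dirichlet":
                res = res_conc.get(n, 0.0)
                flux[0] = d * (c[0] - res) / (dx / 2.0)
                if res_len is not None:
                    # finite well-mixed reservoir: exchange mass with cell 0
                    res_conc[n] = max(res + step * flux[0] / res_len, 0.0)
            # right face: zero flux (wall)
            C[n] = c + step * (flux[1:] - flux[:-1]) / dx
        # reactions
        if rho > 0:
            ph = ph_from_lactate(C.get("lactate", np.zeros(params.n_cells)))
            if "glucose" in C:
                g = C["glucose"]
                uptake = params.vmax_glucose_mM_h * rho * g / (params.km_glucose_mM + g) * step
                uptake = np.minimum(uptake, g)
                C["glucose"] = g - uptake
                if "lactate" in C:
                    C["lactate"] = C["lactate"] + params.lactate_yield * uptake
            if "stress_marker" in C:
                stressed = np.zeros(params.n_cells, dtype=bool)
                if "glucose" in C:
                    stressed |= C["glucose"] < params.stress_glucose_threshold_mM
                stressed |= ph < params.stress_ph_threshold
                C["stress_marker"] = C["stress_marker"] + np.where(
                    stressed, params.stress_release_mM_h * rho * step, 0.0
                )
        for n in names:
            np.clip(C[n], 0.0, None, out=C[n])
        t += step
        while next_out < len(out_times) and t >= out_times[next_out] - 1e-9:
            for n in names:
                frames[n].append(C[n].copy())
            ph_frames.append(ph_from_lactate(C.get("lactate", np.zeros(params.n_cells))))
            next_out += 1

    out_times = out_times[: len(ph_frames)]
    return FieldState(
        x_mm=x,
        t_h=out_times,
        conc={n: np.asarray(frames[n]) for n in names},
        ph=np.asarray(ph_frames),
    )


# ---------------------------------------------------------------------------
# Spectral rendering
# ---------------------------------------------------------------------------


@dataclass
class NoiseSettings:
    """Detector and background model for the renderer.

    Additive Gaussian noise on counts (detector-dominated regime); cosmic-ray
    spikes as 1-3 channel positive outliers with per-spectrum probability
    ``spike_probability``; a slowly varying fluorescence baseline; and glass
    marker bands mixed in by proximity of the focal plane to either window
    (exponential decay with ``glass_decay_mm``).
    """

    sd: float = 1.0
    spike_probability: float = 0.1
    spike_amplitude: tuple = (500.0, 2000.0)
    baseline_amplitude: float = 50.0
    baseline_slope: float = 0.02          # counts per cm^-1
    glass_amplitude: float = 200.0
    glass_decay_mm: float = 0.15

    @classmethod
    def noiseless(cls) -> "NoiseSettings":
        return cls(sd=0.0, spike_probability=0.0, baseline_amplitude=0.0,
                   baseline_slope=0.0, glass_amplitude=0.0)


def _baseline(axis: np.ndarray, noise: NoiseSettings) -> np.ndarray:
    """Broad fluorescence hump plus a gentle slope."""
    if noise.baseline_amplitude == 0 and noise.baseline_slope == 0:
        return np.zeros_like(axis)
    hump = noise.baseline_amplitude * np.exp(-0.5 * ((axis - 900.0) / 260.0) ** 2)
    return hump + noise.baseline_slope * (axis - axis[0])


def _glass(axis: np.ndarray, z_mm: float, noise: NoiseSettings) -> np.ndarray:
    if noise.glass_amplitude == 0:
        return np.zeros_like(axis)
    w_bottom = np.exp(-z_mm / noise.glass_decay_mm)
    w_top = np.exp(-(CHAMBER_DEPTH_MM - z_mm) / noise.glass_decay_mm)
    y = np.zeros_like(axis)
    for comp in GLASS_BOTTOM:
        y += w_bottom * noise.glass_amplitude * comp.profile(axis)
    for comp in GLASS_TOP:
        y += w_top * noise.glass_amplitude * comp.profile(axis)
    return y


def synthesize_spectrum(
    axis: np.ndarray,
    concentrations: Dict[str, float],
    ph: float,
    meta: AcquisitionMeta,
    noise: NoiseSettings,
    rng: np.random.Generator,
    library: Dict[str, AnalyteModel] | None = None,
) -> Spectrum:
    """Render one spectrum from explicit concentrations and pH."""
    if library is None:
        library = build_analyte_library()
    y = np.zeros_like(axis, dtype=float)
    for name, conc in concentrations.items():
        y += library[name].response(axis, conc, ph=ph)
    y += _baseline(axis, noise)
    y += _glass(axis, meta.z_mm, noise)
    if noise.sd > 0:
        y += rng.normal(0.0, noise.sd, size=axis.size)
    if noise.spike_probability > 0 and rng.random() < noise.spike_probability:
        start = rng.integers(0, axis.size - 3)
        width = int(rng.integers(1, 4))
        amp = rng.uniform(*noise.spike_amplitude)
        y[start : start + width] += amp
    return Spectrum(np.asarray(axis, dtype=float), y, meta)


#: Medium composition rendered with every in-chamber spectrum ("1x" units,
#: HEPES in mM).
MEDIUM_COMPOSITION = {"hepes": HEPES_MEDIUM_MM, "medium_background": 1.0, "medium_titratable": 1.0}


def render_spectrum(
    fieldstate: FieldState,
    x: float,
    t: float,
    meta: AcquisitionMeta,
    noise: NoiseSettings | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    library: Dict[str, AnalyteModel] | None = None,
    include_medium: bool = True,
) -> Spectrum:
    """Render the spectrum observed at position ``x`` and time ``t`` of a field."""
    if noise is None:
        noise = NoiseSettings()
    if rng is None:
        if seed is None:
            raise ValueError("provide a seed or an rng")
        rng = np.random.default_rng(seed)
    conc, ph = fieldstate.at(x, t)
    conc = dict(conc)
    if include_medium:
        for name, c in MEDIUM_COMPOSITION.items():
            conc.setdefault(name, c)
    axis = make_axis()
    return synthesize_spectrum(axis, conc, ph, meta, noise, rng, library)


# ---------------------------------------------------------------------------
# Acquisition-design generators
# ---------------------------------------------------------------------------


@dataclass
class ExperimentDesign:
    """Zones x days x replicates acquisition design of the 4-day study."""

    zones: tuple = ("z1", "z2", "z3")
    days: tuple = (1, 2, 3, 4)
    replicates: int = 15
    include_control: bool = True
    cell_line: str = "HEK293T"
    z_mm: float = 0.4

    def __post_init__(self) -> None:
        if not set(self.zones) <= {"z1", "z2", "z3"}:
            raise ValueError("zones must be a subset of {z1, z2, z3}")
        if not set(self.days) <= {1, 2, 3, 4}:
            raise ValueError("days must be a subset of {1, 2, 3, 4}")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def generate_experiment(
    design: ExperimentDesign | None = None,
    seed: int = 0,
    params: ReactionDiffusionParams | None = None,
    noise: NoiseSettings | None = None,
) -> SpectrumSet:
    """Simulate the study once and render the full replicate design.

    One reaction-diffusion run per condition (cells, and a matched no-cell
    control when requested); ``replicates`` spectra at each zone-center
    position on each day. Metadata fully populated.
    """
    if design is None:
        design = ExperimentDesign()
    if params is None:
        params = ReactionDiffusionParams()
    if noise is None:
        noise = NoiseSettings()
    duration = 24.0 * max(design.days)
    rng = stage_rng(seed, "experiment")
    library = build_analyte_library()
    spectra = []
    conditions = [("cells", params)]
    if design.include_control:
        conditions.append(("control", replace(params, cell_density=0.0)))
    for condition, p in conditions:
        fieldstate = simulate_reaction_diffusion(p, duration_h=duration)
        line = design.cell_line if condition == "cells" else "none"
        for day in design.days:
            for zone in design.zones:
                x = zone_center(zone)
                for rep in range(1, design.replicates + 1):
                    meta = AcquisitionMeta(
                        zone=zone, day=day, replicate=rep, x_mm=x,
                        z_mm=design.z_mm, condition=condition, cell_line=line,
                    )
                    spectra.append(
                        render_spectrum(fieldstate, x, 24.0 * day, meta,
                                        noise=noise, rng=rng, library=library)
                    )
    return SpectrumSet.from_spectra(spectra)


def generate_ph_series(
    ph_values: Sequence[float],
    replicates: int = 1,
    seed: int = 0,
    noise: NoiseSettings | None = None,
) -> SpectrumSet:
    """HEPES-buffered medium spectra at the given pH values (pH 4-10 series)."""
    if noise is None:
        noise = NoiseSettings()
    rng = stage_rng(seed, "ph_series")
    library = build_analyte_library()
    axis = make_axis()
    spectra = []
    meta_ph = []
    for ph in ph_values:
        for rep in range(1, replicates + 1):
            meta = AcquisitionMeta(replicate=rep, condition="control")
            spectra.append(
                synthesize_spectrum(axis, dict(MEDIUM_COMPOSITION), float(ph), meta, noise, rng, library)
            )
            meta_ph.append(float(ph))
    sset = SpectrumSet.from_spectra(spectra)
    sset.meta["ph"] = meta_ph
    return sset


def generate_dilution_series(
    analyte: str,
    conc_values: Sequence[float],
    replicates: int = 1,
    seed: int = 0,
    noise: NoiseSettings | None = None,
) -> SpectrumSet:
    """Analyte-in-water spectra at the given concentrations (calibration series)."""
    if noise is None:
        noise = NoiseSettings()
    rng = stage_rng(seed, f"dilution_{analyte}")
    library = build_analyte_library()
    if analyte not in library:
        raise KeyError(f"unknown analyte {analyte!r}")
    axis = make_axis()
    spectra, concs = [], []
    for conc in conc_values:
        if conc < 0:
            raise ValueError("concentrations must be >= 0")
        for rep in range(1, replicates + 1):
            meta = AcquisitionMeta(replicate=rep, condition="control")
            spectra.append(
                synthesize_spectrum(axis, {analyte: float(conc)}, 7.4, meta, noise, rng, library)
            )
            concs.append(float(conc))
    sset = SpectrumSet.from_spectra(spectra)
    sset.meta["concentration_mM"] = concs
    return sset


def generate_zscan(
    z_start: float = 0.0,
    z_end: float = CHAMBER_DEPTH_MM,
    step: float = 0.1,
    seed: int = 0,
    noise: NoiseSettings | None = None,
) -> SpectrumSet:
    """Vertical focus scan through the medium-filled chamber.

    Renders medium spectra at focal heights from ``z_start`` to ``z_end``
    inclusive; glass marker bands mix in by proximity to either window
    (0-1.5 mm at 0.1 mm steps reproduces the 16-spectrum scan).
    """
    if noise is None:
        noise = NoiseSettings()
    n = int(round((z_end - z_start) / step)) + 1
    z_values = z_start + step * np.arange(n)
    rng = stage_rng(seed, "zscan")
    library = build_analyte_library()
    axis = make_axis()
    spectra = []
    for i, z in enumerate(z_values):
        meta = AcquisitionMeta(replicate=i + 1, z_mm=float(z), condition="control")
        spectra.append(
            synthesize_spectrum(axis, dict(MEDIUM_COMPOSITION), 7.4, meta, noise, rng, library)
        )
    return SpectrumSet.from_spectra(spectra)


def generate_chamber_map(
    days: Sequence[int] = (1, 3),
    x_step_mm: float = 1.0,
    replicates: int = 3,
    seed: int = 0,
    params: ReactionDiffusionParams | None = None,
    noise: NoiseSettings | None = None,
) -> SpectrumSet:
    """Whole-chamber x-axis imaging on the given days (gradient mapping)."""
    if params is None:
        params = ReactionDiffusionParams()
    if noise is None:
        noise = NoiseSettings()
    fieldstate = simulate_reaction_diffusion(params, duration_h=24.0 * max(days))
    rng = stage_rng(seed, "chamber_map")
    library = build_analyte_library()
    x_values = np.arange(0.5, CHAMBER_LENGTH_MM - 0.5 + 1e-9, x_step_mm)
    spectra = []
    for day in days:
        for x in x_values:
            for rep in range(1, replicates + 1):
                meta = AcquisitionMeta(
                    zone=zone_of(float(x)), day=int(day), replicate=rep,
                    x_mm=float(x), z_mm=0.4, condition="cells", cell_line="HEK293T",
                )
                spectra.append(
                    render_spectrum(fieldstate, float(x), 24.0 * day, meta,
                                    noise=noise, rng=rng, library=library)
                )
    return SpectrumSet.from_spectra(spectra)


def generate_adenine_diffusion(
    t_min: float = 10.0,
    x_values: Sequence[float] | None = None,
    replicates: int = 5,
    seed: int = 0,
    noise: NoiseSettings | None = None,
) -> SpectrumSet:
    """Adenine (1 mM reservoir) diffusing into the cell-free chamber.

    Reproduces the transport validation: spectra along x after ``t_min``
    minutes show the 725 cm^-1 band decaying with distance from the reservoir.
    """
    if noise is None:
        noise = NoiseSettings()
    params = ReactionDiffusionParams(
        n_cells=150,
        cell_density=0.0,
        reservoir_mM={"adenine": 1.0},
        initial_mM={"adenine": 0.0},
        reservoir_volume_ratio=None,  # large adenine stock: constant source
        output_dt_h=t_min / 60.0 / 4.0,
    )
    fieldstate = simulate_reaction_diffusion(params, duration_h=t_min / 60.0)
    if x_values is None:
        x_values = np.arange(0.25, 2.01, 0.25)
    rng = stage_rng(seed, "adenine_diffusion")
    library = build_analyte_library()
    spectra = []
    for x in x_values:
        for rep in range(1, replicates + 1):
            meta = AcquisitionMeta(zone=zone_of(float(x)), replicate=rep, x_mm=float(x),
                                   z_mm=0.4, condition="control")
            spectra.append(
                render_spectrum(fieldstate, float(x), t_min / 60.0, meta,
                                noise=noise, rng=rng, library=library, include_medium=False)
            )
    return SpectrumSet.from_spectra(spectra)
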