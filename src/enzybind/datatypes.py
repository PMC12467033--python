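"""Measurement containers shared by the analysis stages.

Each container validates its type invariants on construction so that every
downstream operation can assume well-formed input.  Units are fixed by
convention: inhibitor concentrations in μg/mL, substrate concentrations in
mmol/L, quencher concentrations in mol/L, temperatures in kelvin,
wavelengths in nm and wavenumbers in cm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvariantError


def _finite(name: str, *values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise InvariantError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class AssayAbsorbances:
    """The four absorbance readings of one chromogenic inhibition assay.

    a1: sample group (enzyme + inhibitor + substrate);
    a2: sample control (enzyme replaced by buffer);
    a3: blank control (no inhibitor);
    a4: reagent blank.
    """

    a1: float
    a2: float
    a3: float
    a4: float

    def __post_init__(self):
        _finite("AssayAbsorbances", self.a1, self.a2, self.a3, self.a4)


@dataclass(frozen=True)
class ViabilityAbsorbances:
    """MTT-assay absorbances: sample well, blank control (cells, no drug)
    and solvent control (no cells, no drug)."""

    a_sample: float
    a_control: float
    a_blank: float

    def __post_init__(self):
        _finite("ViabilityAbsorbances", self.a_sample, self.a_control, self.a_blank)


@dataclass(frozen=True)
class DoseResponseSeries:
    """Percent inhibition versus inhibitor concentration for one system."""

    compound: str
    enzyme: str  # "alpha_amylase" | "alpha_glucosidase"
    concentrations: tuple[float, ...]  # μg/mL, strictly increasing, >= 0
    inhibition: tuple[float, ...]  # percent
    replicate_sd: tuple[float, ...] | None = None

    def __post_init__(self):
        c = np.asarray(self.concentrations, float)
        y = np.asarray(self.inhibition, float)
        if c.size != y.size or c.size == 0:
            raise InvariantError("DoseResponseSeries: mismatched or empty arrays")
        if np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise InvariantError(
                "DoseResponseSeries: concentrations must be >= 0 and strictly increasing"
            )
        _finite("DoseResponseSeries.inhibition", *y)
        if self.replicate_sd is not None and len(self.replicate_sd) != c.size:
            raise InvariantError("DoseResponseSeries: replicate_sd length mismatch")


@dataclass(frozen=True)
class KineticSeries:
    """Initial velocity vs substrate concentration at one inhibitor level."""

    inhibitor_conc: float  # μg/mL
    substrate: tuple[float, ...]  # mmol/L, all > 0
    velocity: tuple[float, ...]  # ΔOD/min, all > 0

    def __post_init__(self):
        s = np.asarray(self.substrate, float)
        v = np.asarray(self.velocity, float)
        if s.size != v.size:
            raise InvariantError("KineticSeries: substrate/velocity length mismatch")
        if np.unique(s).size < 3:
            raise InvariantError(
                "KineticSeries: need >= 3 distinct substrate concentrations"
            )
        if np.any(s <= 0) or np.any(v <= 0):
            raise InvariantError("KineticSeries: substrate and velocity must be > 0")
        _finite("KineticSeries", *s, *v)
        if self.inhibitor_conc < 0:
            raise InvariantError("KineticSeries: inhibitor_conc must be >= 0")


@dataclass(frozen=True)
class ReversibilitySeries:
    """Velocity vs enzyme activity at one inhibitor concentration.

    In a reversibility experiment the enzyme concentration (U/L) is varied at
    fixed inhibitor; a reversible inhibitor yields lines through the origin
    whose slope falls as inhibitor rises.
    """

    inhibitor_conc: float  # μg/mL
    enzyme_activity: tuple[float, ...]  # U/L
    velocity: tuple[float, ...]  # ΔOD/min

    def __post_init__(self):
        e = np.asarray(self.enzyme_activity, float)
        v = np.asarray(self.velocity, float)
        if e.size != v.size or e.size < 3:
            raise InvariantError("ReversibilitySeries: need >= 3 matched points")
        if np.any(e <= 0):
            raise InvariantError("ReversibilitySeries: enzyme activities must be > 0")
        _finite("ReversibilitySeries", *e, *v)


@dataclass(frozen=True)
class QuenchTitration:
    """Fluorescence titration of the enzyme by a quencher at one temperature.

    The first point must be the quencher-free reference (Q = 0), whose
    intensity defines F0.  Optional per-point absorbances at the excitation
    and emission wavelengths support inner-filter correction.
    """

    temperature: float  # K
    quencher_conc: tuple[float, ...]  # mol/L, Q[0] == 0, strictly increasing
    intensity: tuple[float, ...]  # observed fluorescence, > 0
    a_ex: tuple[float, ...] | None = None
    a_em: tuple[float, ...] | None = None

    def __post_init__(self):
        q = np.asarray(self.quencher_conc, float)
        f = np.asarray(self.intensity, float)
        if q.size != f.size or q.size < 2:
            raise InvariantError("QuenchTitration: need >= 2 matched points")
        if q[0] != 0:
            raise InvariantError("QuenchTitration: first point must have Q = 0")
        if np.any(np.diff(q) <= 0):
            raise InvariantError("QuenchTitration: Q must be strictly increasing")
        if np.any(f <= 0):
            raise InvariantError("QuenchTitration: intensities must be > 0")
        _finite("QuenchTitration", *q, *f)
        if self.temperature <= 0:
            raise InvariantError("QuenchTitration: temperature must be > 0 K")
        for name, arr in (("a_ex", self.a_ex), ("a_em", self.a_em)):
            if arr is not None:
                a = np.asarray(arr, float)
                if a.size != q.size:
                    raise InvariantError(f"QuenchTitration: {name} length mismatch")
                if np.any(a < 0):
                    raise InvariantError(f"QuenchTitration: {name} must be >= 0")

    @property
    def f0(self) -> float:
        """Reference intensity at Q = 0."""
        return float(self.intensity[0])


@dataclass(frozen=True)
class SpectrumSeries:
    """A concentration series of 1-D spectra on a common wavelength grid.

    mode 'sync15'/'sync60' are synchronous-scan channels (Δλ = 15 nm probes
    tyrosine, Δλ = 60 nm tryptophan); 'emission' is an ordinary emission scan.
    The first concentration must be 0 (protein alone).
    """

    mode: str  # sync15 | sync60 | emission
    concentrations: tuple[float, ...]  # μg/mL, first is 0
    wavelengths: tuple[float, ...]  # nm, strictly increasing
    intensities: tuple[tuple[float, ...], ...]  # one row per concentration

    def __post_init__(self):
        if self.mode not in ("sync15", "sync60", "emission"):
            raise InvariantError(f"SpectrumSeries: unknown mode {self.mode!r}")
        wl = np.asarray(self.wavelengths, float)
        if np.any(np.diff(wl) <= 0):
            raise InvariantError("SpectrumSeries: wavelength grid must increase")
        if len(self.concentrations) == 0 or self.concentrations[0] != 0:
            raise InvariantError("SpectrumSeries: first concentration must be 0")
        if len(self.intensities) != len(self.concentrations):
            raise InvariantError("SpectrumSeries: one spectrum per concentration")
        for row in self.intensities:
            if len(row) != wl.size:
                raise InvariantError("SpectrumSeries: spectra must share the grid")
            _finite("SpectrumSeries.intensities", *row)


@dataclass(frozen=True)
class EEM:
    """Excitation-emission matrix, intensity indexed (excitation, emission)."""

    ex_grid: tuple[float, ...]  # nm
    em_grid: tuple[float, ...]  # nm
    intensity: tuple[tuple[float, ...], ...]  # shape (len(ex), len(em))

    def __post_init__(self):
        ex = np.asarray(self.ex_grid, float)
        em = np.asarray(self.em_grid, float)
        if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
            raise InvariantError("EEM: grids must be strictly increasing")
        z = np.asarray(self.intensity, float)
        if z.shape != (ex.size, em.size):
            raise InvariantError(
                f"EEM: intensity shape {z.shape} != ({ex.size}, {em.size})"
            )
        if not np.all(np.isfinite(z)):
            raise InvariantError("EEM: intensities must be finite")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.intensity, float)


@dataclass(frozen=True)
class FtirSpectrum:
    """Infrared absorbance vs wavenumber; must cover the amide-I window."""

    wavenumber: tuple[float, ...]  # cm^-1, strictly monotone
    absorbance: tuple[float, ...]

    def __post_init__(self):
        x = np.asarray(self.wavenumber, float)
        y = np.asarray(self.absorbance, float)
        if x.size != y.size or x.size < 3:
            raise InvariantError("FtirSpectrum: need >= 3 matched points")
        d = np.diff(x)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvariantError("FtirSpectrum: wavenumber grid must be monotone")
        if not np.all(np.isfinite(y)):
            raise InvariantError("FtirSpectrum: absorbances must be finite")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants used across the pipeline.

    tau0: fluorophore lifetime without quencher (s); kq_static_threshold: the
    bimolecular quenching rate above which diffusional quenching is
    implausible (L/mol/s); km_constancy_tol: relative Km spread treated as
    "unchanged" when classifying inhibition type.
    """

    tau0: float = 1e-8
    gas_constant: float = 8.314  # J/mol/K
    kq_static_threshold: float = 2.0e10
    km_constancy_tol: float = 0.05
    shift_threshold_nm: float | None = None  # None -> one grid step
    random_seed: int = 0
    regression_mode: str = "lineweaver_burk"  # or "nonlinear"

    def __post_init__(self):
        for name in ("tau0", "gas_constant", "kq_static_threshold", "km_constancy_tol"):
            if getattr(self, name) <= 0:
                raise InvariantError(f"AnalysisConfig: {name} must be positive")
        if self.regression_mode not in ("lineweaver_burk", "nonlinear"):
            raise InvariantError(
                f"AnalysisConfig: unknown regression_mode {self.regression_mode!r}"
            )
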