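"""Synthetic assay data with known ground truth for every pipeline stage.

The raw curves behind the published tables are not deposited, so each
analysis stage is validated against data generated from the exact forward
model it inverts: Michaelis-Menten kinetics under the four inhibition
modes, static-quenching titrations obeying the double-log binding law,
Van't Hoff-consistent Ka(T) series, logistic dose-response curves, Gaussian
synchronous/EEM spectra, and amide-I bands as Gaussian mixtures with known
class areas.  At zero noise every generator/analyser pair is an exact
inverse; the additive Gaussian noise model (replicate scatter) is the
simplest one consistent with the mean ± s replicate reporting convention of
this assay family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    EEM,
    DoseResponseSeries,
    FtirSpectrum,
    KineticSeries,
    QuenchTitration,
    SpectrumSeries,
)
from .errors import InvariantError, ParameterError
from .ftir import AMIDE_I_WINDOW
from .thermo import R_GAS

# default grids: the study conditions
DEFAULT_SUBSTRATE_GRID = (2.5, 5.0, 7.5, 10.0)  # mmol/L
DEFAULT_TEMPERATURES = (298.0, 304.0, 310.0)  # K

_REQUIRED_PARAMS = {
    "kinetics": {"inhibition_type", "km", "vmax", "ki"},
    "quench": set(),  # ksv XOR (ka, n), checked in the generator
    "vant_hoff": {"dh", "ds"},
    "dose_response": {"ic50", "hill"},
    "synchronous": {"center_nm", "sigma_nm", "amplitude", "quench_factors"},
    "eem": {"peaks"},
    "ftir": {"peaks"},
}


@dataclass(frozen=True)
class GroundTruth:
    """Stage label plus the parameter map a generator realizes.

    ``noise_sd`` is additive Gaussian scatter in the stage's signal units
    (velocity, intensity or absorbance); ``seed`` fixes the noise stream.
    """

    stage: str
    parameters: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.stage not in _REQUIRED_PARAMS:
            raise InvariantError(f"GroundTruth: unknown stage {self.stage!r}")
        if self.noise_sd < 0:
            raise InvariantError("GroundTruth: noise_sd must be >= 0")
        missing = _REQUIRED_PARAMS[self.stage] - set(self.parameters)
        if missing:
            raise InvariantError(
                f"GroundTruth({self.stage}): missing parameters {sorted(missing)}"
            )

    def _rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def __getitem__(self, key):
        return self.parameters[key]


def _noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(shape)
    return rng.normal(0.0, sd, size=shape)


def inhibited_velocity(
    s, i, km, vmax, ki, kis=None, inhibition_type: str = "mixed"
):
    """Initial velocity under the four classical inhibition rate laws.

    mixed:          v = Vmax·S / (Km·(1+I/Ki) + S·(1+I/Kis))
    noncompetitive: Kis = Ki (equal affinity for E and ES)
    competitive:    v = Vmax·S / (Km·(1+I/Ki) + S)
    uncompetitive:  v = Vmax·S / (Km + S·(1+I/Kis)); Kis defaults to Ki
    """
    s = np.asarray(s, float)
    if km <= 0 or vmax <= 0 or ki <= 0 or (kis is not None and kis <= 0):
        raise ParameterError("kinetic constants must be positive")
    if inhibition_type == "mixed":
        if kis is None:
            raise ParameterError("mixed inhibition requires Kis")
        denom = km * (1 + i / ki) + s * (1 + i / kis)
    elif inhibition_type == "noncompetitive":
        denom = km * (1 + i / ki) + s * (1 + i / ki)
    elif inhibition_type == "competitive":
        denom = km * (1 + i / ki) + s
    elif inhibition_type == "uncompetitive":
        kis_eff = ki if kis is None else kis
        denom = km + s * (1 + i / kis_eff)
    else:
        raise ParameterError(f"unknown inhibition type {inhibition_type!r}")
    return vmax * s / denom


def gen_kinetics(
    truth: GroundTruth,
    substrate_grid=DEFAULT_SUBSTRATE_GRID,
    inhibitor_grid=(0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
) -> list[KineticSeries]:
    """One velocity series per inhibitor concentration."""
    if len(substrate_grid) == 0 or len(inhibitor_grid) == 0:
        raise ParameterError("gen_kinetics: grids must be non-empty")
    rng = truth._rng()
    p = truth.parameters
    series = []
    for i in inhibitor_grid:
        v = inhibited_velocity(
            substrate_grid, i, p["km"], p["vmax"], p["ki"],
            p.get("kis"), p["inhibition_type"],
        )
        v = v + _noise(rng, truth.noise_sd, v.shape)
        v = np.maximum(v, 1e-9 * p["vmax"])  # container requires v > 0
        series.append(
            KineticSeries(float(i), tuple(map(float, substrate_grid)), tuple(v))
        )
    return series


def gen_quench_titration(
    truth: GroundTruth,
    f0: float,
    q_grid,
    temperature: float = 298.0,
    inner_filter=None,
) -> QuenchTitration:
    """Quenching titration in Stern-Volmer or binding (Ka, n) mode.

    Ksv mode generates F = F0/(1+Ksv·Q) ('linear' form) or F = F0·e^(−Ksv·Q)
    ('exponential' form, parameter ``sv_model``); (Ka, n) mode generates
    (F0−F)/F = Ka·Qⁿ.  ``inner_filter`` may be a per-point sequence of
    (Aex, Aem) pairs or one pair applied to every point; the emitted
    intensity is then F·e^(−(Aex+Aem)/2), which inner-filter correction
    inverts exactly.
    """
    p = truth.parameters
    has_ksv = "ksv" in p
    has_kan = "ka" in p or "n" in p
    if has_ksv == has_kan or ("ka" in p) != ("n" in p):
        raise ParameterError(
            "gen_quench_titration: supply exactly one of ksv or (ka, n)"
        )
    if f0 <= 0:
        raise ParameterError("gen_quench_titration: F0 must be positive")
    q = np.asarray(q_grid, float)
    if q.size == 0 or np.any(q < 0) or np.any(np.diff(q) <= 0):
        raise ParameterError("gen_quench_titration: Q grid must be "
                             "non-negative and increasing")
    if q[0] != 0:
        q = np.concatenate([[0.0], q])
    if has_ksv:
        if p.get("sv_model", "linear") == "exponential":
            f = f0 * np.exp(-p["ksv"] * q)
        else:
            f = f0 / (1.0 + p["ksv"] * q)
    else:
        f = f0 / (1.0 + p["ka"] * np.power(q, p["n"], where=q > 0, out=np.zeros_like(q)))
    rng = truth._rng()
    f = f + _noise(rng, truth.noise_sd, f.shape)
    f = np.maximum(f, 1e-9 * f0)
    a_ex = a_em = None
    if inner_filter is not None:
        pairs = np.asarray(inner_filter, float)
        if pairs.ndim == 1:
            pairs = np.tile(pairs, (q.size, 1))
        if pairs.shape != (q.size, 2) or np.any(pairs < 0):
            raise ParameterError(
                "gen_quench_titration: inner_filter must be (Aex, Aem) >= 0 "
                "per point"
            )
        f = f * np.exp(-(pairs[:, 0] + pairs[:, 1]) / 2.0)
        a_ex, a_em = tuple(pairs[:, 0]), tuple(pairs[:, 1])
    return QuenchTitration(
        temperature=temperature,
        quencher_conc=tuple(q),
        intensity=tuple(f),
        a_ex=a_ex,
        a_em=a_em,
    )


def gen_vant_hoff(
    truth: GroundTruth, t_grid=DEFAULT_TEMPERATURES
) -> list[tuple[float, float]]:
    """(T, Ka) pairs exactly on the Van't Hoff line
    Ka(T) = exp(−ΔH/(R·T) + ΔS/R); optional noise acts on ln Ka."""
    t = np.asarray(t_grid, float)
    if np.unique(t).size < 2:
        raise ParameterError("gen_vant_hoff: need >= 2 distinct temperatures")
    p = truth.parameters
    ln_ka = -p["dh"] / (R_GAS * t) + p["ds"] / R_GAS
    ln_ka = ln_ka + _noise(truth._rng(), truth.noise_sd, ln_ka.shape)
    return [(float(ti), float(np.exp(l))) for ti, l in zip(t, ln_ka)]


def gen_dose_response(
    truth: GroundTruth,
    conc_grid,
    compound: str = "synthetic",
    enzyme: str = "alpha_amylase",
) -> DoseResponseSeries:
    """Logistic dose-response: inhibition = 100/(1+(IC50/c)^hill) + noise."""
    p = truth.parameters
    if p["ic50"] <= 0:
        raise ParameterError("gen_dose_response: IC50 must be positive")
    c = np.asarray(conc_grid, float)
    with np.errstate(divide="ignore"):
        y = np.where(c > 0, 100.0 / (1.0 + (p["ic50"] / np.maximum(c, 1e-300)) ** p["hill"]), 0.0)
    y = y + _noise(truth._rng(), truth.noise_sd, y.shape)
    return DoseResponseSeries(
        compound=compound,
        enzyme=enzyme,
        concentrations=tuple(c),
        inhibition=tuple(y),
    )


def _gaussian(x, center, sigma):
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gen_synchronous(truth: GroundTruth) -> SpectrumSeries:
    """Synchronous-scan series: one Gaussian peak whose center moves by
    ``center_step_nm`` per concentration index and whose amplitude scales by
    the supplied per-concentration quench factor."""
    p = truth.parameters
    quench = np.asarray(p["quench_factors"], float)
    concentrations = tuple(p.get("concentrations", tuple(range(quench.size))))
    wl = np.arange(
        p.get("wl_min", 250.0), p.get("wl_max", 360.0) + 1e-9, p.get("wl_step", 1.0)
    )
    step = p.get("center_step_nm", 0.0)
    rng = truth._rng()
    rows = []
    for idx, qf in enumerate(quench):
        y = p["amplitude"] * qf * _gaussian(wl, p["center_nm"] + idx * step, p["sigma_nm"])
        y = y + _noise(rng, truth.noise_sd, y.shape)
        rows.append(tuple(y))
    return SpectrumSeries(
        mode=p.get("mode", "sync60"),
        concentrations=concentrations,
        wavelengths=tuple(wl),
        intensities=tuple(rows),
    )


def gen_eem(truth: GroundTruth) -> EEM:
    """Excitation-emission matrix as a sum of 2-D Gaussians, optionally with
    a first-order Rayleigh ridge along Em = Ex."""
    p = truth.parameters
    ex = np.arange(p.get("ex_min", 200.0), p.get("ex_max", 420.0) + 1e-9, p.get("step", 2.0))
    em = np.arange(p.get("em_min", 280.0), p.get("em_max", 460.0) + 1e-9, p.get("step", 2.0))
    ex2d, em2d = np.meshgrid(ex, em, indexing="ij")
    z = np.zeros_like(ex2d)
    for peak in p["peaks"]:
        z = z + peak["amplitude"] * _gaussian(ex2d, peak["ex"], peak.get("sigma_ex", 10.0)) * _gaussian(
            em2d, peak["em"], peak.get("sigma_em", 12.0)
        )
    if p.get("rayleigh_amplitude", 0.0):
        z = z + p["rayleigh_amplitude"] * _gaussian(em2d - ex2d, 0.0, p.get("rayleigh_sigma", 6.0))
    z = z + _noise(truth._rng(), truth.noise_sd, z.shape)
    return EEM(tuple(ex), tuple(em), tuple(map(tuple, z)))


def gen_ftir(truth: GroundTruth) -> FtirSpectrum:
    """Amide-I region as a Gaussian mixture with specified per-peak areas.

    Each peak dict carries (center cm⁻¹ within 1600-1700, sigma, area);
    optional ``baseline_offset``/``baseline_slope`` add a straight line that
    the analysis baseline step removes exactly.
    """
    p = truth.parameters
    lo, hi = AMIDE_I_WINDOW
    x = np.arange(p.get("wn_min", 1560.0), p.get("wn_max", 1740.0) + 1e-9, p.get("wn_step", 1.0))
    y = np.zeros_like(x)
    for peak in p["peaks"]:
        if not (lo <= peak["center"] <= hi):
            raise ParameterError(
                f"gen_ftir: peak center {peak['center']} outside [{lo}, {hi}]"
            )
        amp = peak["area"] / (peak["sigma"] * np.sqrt(2.0 * np.pi))
        y = y + amp * _gaussian(x, peak["center"], peak["sigma"])
    y = y + p.get("baseline_offset", 0.0) + p.get("baseline_slope", 0.0) * (x - x[0])
    y = y + _noise(truth._rng(), truth.noise_sd, y.shape)
    return FtirSpectrum(tuple(x), tuple(y))


def gen_spectra(truth: GroundTruth, kind: str):
    """Dispatch to the synchronous / EEM / FTIR spectrum generators."""
    if kind == "synchronous":
        return gen_synchronous(truth)
    if kind == "eem":
        return gen_eem(truth)
    if kind == "ftir":
        return gen_ftir(truth)
    raise ParameterError(f"gen_spectra: unknown kind {kind!r}")
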