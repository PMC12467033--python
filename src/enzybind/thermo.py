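"""Van't Hoff binding thermodynamics and interaction-force classification.

The temperature dependence of the binding constant follows
ln Ka = −ΔH⁰/(R·T) + ΔS⁰/R, so an OLS regression of ln Ka on 1/T yields the
standard enthalpy (−R·slope) and entropy (R·intercept) of complex
formation.  The free energy is ΔG⁰(T) = −R·T·ln Ka = ΔH⁰ − T·ΔS⁰.  The sign
pattern of (ΔH⁰, ΔS⁰) identifies the dominant intermolecular force:
both positive -> hydrophobic; both negative -> hydrogen bonding and van der
Waals; ΔH⁰ < 0 with ΔS⁰ > 0 -> electrostatic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvariantError

logger = logging.getLogger(__name__)

R_GAS = 8.314  # J/mol/K


@dataclass(frozen=True)
class VantHoffFit:
    """Regression results of ln Ka on 1/T."""

    dh: float  # ΔH⁰, J/mol
    ds: float  # ΔS⁰, J/mol/K
    r_squared: float
    se_dh: float
    se_ds: float


@dataclass(frozen=True)
class ThermoFit:
    """Full thermodynamic profile of one enzyme-ligand system."""

    dh: float
    ds: float
    dg_by_t: dict[float, float]  # T (K) -> ΔG⁰ (J/mol), from −RT ln Ka
    dg_from_enthalpy_by_t: dict[float, float]  # ΔH⁰ − T·ΔS⁰ diagnostic
    r_squared: float
    force: str


def vant_hoff_fit(pairs: list[tuple[float, float]], gas_constant: float = R_GAS) -> VantHoffFit:
    """Fit ΔH⁰ and ΔS⁰ from (temperature K, Ka L/mol) pairs."""
    if len(pairs) < 2:
        raise InvariantError("vant_hoff_fit: need >= 2 temperatures")
    t = np.array([p[0] for p in pairs], float)
    ka = np.array([p[1] for p in pairs], float)
    if np.unique(t).size != t.size:
        raise InvariantError("vant_hoff_fit: temperatures must be distinct")
    if np.any(t <= 0):
        raise InvariantError("vant_hoff_fit: temperatures must be positive")
    if np.any(ka <= 0):
        raise InvariantError("vant_hoff_fit: Ka values must be positive")
    res = stats.linregress(1.0 / t, np.log(ka))
    r2 = float(res.rvalue**2) if t.size > 2 else 1.0
    return VantHoffFit(
        dh=float(-gas_constant * res.slope),
        ds=float(gas_constant * res.intercept),
        r_squared=r2,
        se_dh=float(gas_constant * res.stderr) if t.size > 2 else 0.0,
        se_ds=float(gas_constant * res.intercept_stderr) if t.size > 2 else 0.0,
    )


def gibbs_free_energy(
    temperature: float, ka: float, gas_constant: float = R_GAS
) -> float:
    """ΔG⁰ = −R·T·ln Ka (J/mol)."""
    if temperature <= 0:
        raise InvariantError("gibbs_free_energy: temperature must be positive")
    if ka <= 0:
        raise InvariantError("gibbs_free_energy: Ka must be positive")
    return -gas_constant * temperature * math.log(ka)


def gibbs_from_enthalpy(
    temperature: float, dh: float, ds: float
) -> float:
    """Consistency variant ΔG⁰ = ΔH⁰ − T·ΔS⁰ (J/mol)."""
    return dh - temperature * ds


def classify_forces(dh: float, ds: float, epsilon: float = 1e-6) -> str:
    """Dominant intermolecular force from the signs of ΔH⁰ and ΔS⁰.

    Values within ``epsilon`` of zero are flagged as 'boundary' (the sign
    rules are strict); the pattern ΔH⁰ > 0 with ΔS⁰ < 0 has no assigned
    force and returns 'out_of_ruleset'.
    """
    if not (math.isfinite(dh) and math.isfinite(ds)):
        raise InvariantError("classify_forces: inputs must be finite")
    if abs(dh) < epsilon or abs(ds) < epsilon:
        logger.warning(
            "classify_forces: |ΔH| or |ΔS| below epsilon=%g; sign rule is "
            "strict, returning 'boundary'", epsilon,
        )
        return "boundary"
    if dh > 0 and ds > 0:
        return "hydrophobic"
    if dh < 0 and ds < 0:
        return "hbond_vdw"
    if dh < 0 and ds > 0:
        return "electrostatic"
    return "out_of_ruleset"


def thermodynamic_profile(
    pairs: list[tuple[float, float]], gas_constant: float = R_GAS
) -> ThermoFit:
    """Van't Hoff fit plus per-temperature ΔG⁰ and force classification."""
    fit = vant_hoff_fit(pairs, gas_constant)
    dg = {t: gibbs_free_energy(t, ka, gas_constant) for t, ka in pairs}
    dg_h = {t: gibbs_from_enthalpy(t, fit.dh, fit.ds) for t, _ in pairs}
    return ThermoFit(
        dh=fit.dh,
        ds=fit.ds,
        dg_by_t=dg,
        dg_from_enthalpy_by_t=dg_h,
        r_squared=fit.r_squared,
        force=classify_forces(fit.dh, fit.ds),
    )
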