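"""Fluorescence quenching and ligand-binding analysis.

A titration of the enzyme's intrinsic fluorescence by a ligand is analysed
in three steps: (1) inner-filter correction Fcor = Fobs·e^((Aex+Aem)/2)
removes attenuation by the absorbing ligand; (2) the Stern-Volmer relation
F0/F = 1 + Ksv·[Q] (or its exponential variant F0/F = e^(Ksv·[Q]) for
upward-curved plots) yields the quenching constant Ksv and the bimolecular
rate constant Kq = Ksv/τ0, whose magnitude and temperature dependence
classify the mechanism as static (complex-forming) or dynamic
(collisional); (3) the double-logarithmic plot
log[(F0−F)/F] = log Ka + n·log[Q] yields the binding constant Ka and the
number of binding sites n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .datatypes import QuenchTitration
from .errors import DataQualityError, InvariantError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuenchResult:
    """Stern-Volmer analysis of one titration."""

    ksv: float  # L/mol
    kq: float  # L/mol/s, Ksv / tau0
    model: str  # "linear" | "exponential"
    r_squared: float
    curvature_score: float  # relative RSS improvement of exponential form
    temperature: float  # K

    def __post_init__(self):
        if self.model not in ("linear", "exponential"):
            raise InvariantError(f"unknown Stern-Volmer model {self.model!r}")


@dataclass(frozen=True)
class BindingFit:
    """Double-log binding parameters at one temperature."""

    ka: float  # L/mol
    n: float  # binding-site count
    r_squared: float
    temperature: float

    def __post_init__(self):
        if self.ka <= 0:
            raise InvariantError("BindingFit: Ka must be positive")


def inner_filter_correct(t: QuenchTitration) -> QuenchTitration:
    """Undo the inner-filter attenuation pointwise.

    Returns a new titration with Fcor = Fobs·e^((Aex+Aem)/2) and the
    absorbances zeroed (so a second application is the identity).  If either
    absorbance series is absent the titration passes through unchanged with
    a logged warning.
    """
    if t.a_ex is None or t.a_em is None:
        logger.warning(
            "inner_filter_correct: absorbances missing; returning data uncorrected"
        )
        return t
    a_ex = np.asarray(t.a_ex, float)
    a_em = np.asarray(t.a_em, float)
    f = np.asarray(t.intensity, float) * np.exp((a_ex + a_em) / 2.0)
    zeros = tuple(0.0 for _ in t.quencher_conc)
    return replace(t, intensity=tuple(f), a_ex=zeros, a_em=zeros)


def stern_volmer_fit(
    t: QuenchTitration, tau0: float = 1e-8, min_improvement: float = 0.05
) -> QuenchResult:
    """Fit both Stern-Volmer forms and select by residual sum of squares.

    The linear form F0/F = 1 + Ksv·[Q] and the exponential form
    F0/F = e^(Ksv·[Q]) are both fitted by OLS (the latter on ln(F0/F)).
    The exponential form is selected only when it reduces the RSS of the
    ratio by more than ``min_improvement`` (guards against overfitting
    noise); ``curvature_score`` reports that relative improvement.
    """
    q = np.asarray(t.quencher_conc, float)
    f = np.asarray(t.intensity, float)
    if q.size < 4:
        raise InvariantError("stern_volmer_fit: need >= 4 titration points")
    ratio = t.f0 / f
    if np.any(ratio < 1.0 - 1e-12):
        raise DataQualityError(
            "F0/F < 1 at some points: fluorescence enhancement, not quenching"
        )
    lin = stats.linregress(q, ratio)
    rss_lin = float(np.sum((ratio - (lin.intercept + lin.slope * q)) ** 2))
    exp = stats.linregress(q, np.log(ratio))
    rss_exp = float(
        np.sum((ratio - np.exp(exp.intercept + exp.slope * q)) ** 2)
    )
    scale = float(np.sum((ratio - ratio.mean()) ** 2))
    if rss_lin <= max(1e-15 * scale, 0.0):
        curvature = 0.0
    else:
        curvature = (rss_lin - rss_exp) / rss_lin
    if curvature > min_improvement:
        model, res, r2 = "exponential", exp, float(exp.rvalue**2)
    else:
        model, res, r2 = "linear", lin, float(lin.rvalue**2)
    ksv = float(max(res.slope, 0.0))
    return QuenchResult(
        ksv=ksv,
        kq=ksv / tau0,
        model=model,
        r_squared=r2,
        curvature_score=float(curvature),
        temperature=t.temperature,
    )


def classify_mechanism(
    results: list[QuenchResult], threshold: float = 2.0e10
) -> str:
    """Quenching mechanism from the temperature trend of Ksv and from Kq.

    Static quenching (ground-state complex) shows Ksv falling with
    temperature and Kq far above the diffusion-controlled ceiling
    ``threshold``; a falling Ksv with an exponential (upward-curved)
    Stern-Volmer plot indicates mixed quenching with the static component
    dominant; a rising Ksv or small Kq indicates dynamic (collisional)
    quenching.  Conflicting evidence returns 'indeterminate'.
    """
    if len(results) < 2:
        raise InvariantError("classify_mechanism: need >= 2 temperatures")
    results = sorted(results, key=lambda r: r.temperature)
    temps = [r.temperature for r in results]
    if len(set(temps)) != len(temps):
        raise InvariantError("classify_mechanism: temperatures must be distinct")
    ksv = np.array([r.ksv for r in results])
    kq = np.array([r.kq for r in results])
    decreasing = bool(np.all(np.diff(ksv) < 0))
    increasing = bool(np.all(np.diff(ksv) > 0))
    fast = bool(np.all(kq > threshold))
    any_exponential = any(r.model == "exponential" for r in results)
    if increasing or not fast:
        return "dynamic"
    if decreasing and fast and not any_exponential:
        return "static"
    if decreasing and fast and any_exponential:
        return "mixed_static_dominant"
    return "indeterminate"


def double_log_fit(t: QuenchTitration) -> BindingFit:
    """Binding constant and stoichiometry from the double-log plot.

    OLS of log10[(F0−F)/F] on log10[Q] over the Q > 0 points; the slope is
    the binding-site number n and 10^intercept the binding constant Ka
    (L/mol, hence Q must be molar).
    """
    q = np.asarray(t.quencher_conc, float)
    f = np.asarray(t.intensity, float)
    mask = q > 0
    bad = [int(i) + 1 for i in np.nonzero(mask & (f >= t.f0))[0]]
    if bad:
        raise DataQualityError(
            f"F >= F0 at titration point(s) {bad}: double-log plot undefined"
        )
    x = np.log10(q[mask])
    y = np.log10((t.f0 - f[mask]) / f[mask])
    res = stats.linregress(x, y)
    return BindingFit(
        ka=float(10.0**res.intercept),
        n=float(res.slope),
        r_squared=float(res.rvalue**2),
        temperature=t.temperature,
    )
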