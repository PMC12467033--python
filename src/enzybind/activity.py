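"""Activity-level analysis: inhibition rates, cell viability, IC50,
reversibility verdicts and stability profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datatypes import AssayAbsorbances, DoseResponseSeries, ReversibilitySeries, ViabilityAbsorbances
from .errors import BracketingError, FitError, InvariantError


def inhibition_rate(absorbances: AssayAbsorbances) -> float:
    """Percent inhibition from the four assay absorbances.

    rate = (1 − (A1 − A2)/(A3 − A4))·100.  The value may legitimately fall
    below 0 (activation) or above 100.
    """
    denom = absorbances.a3 - absorbances.a4
    if denom == 0:
        raise InvariantError(
            "inhibition_rate: blank pair A3 - A4 is zero; rate undefined"
        )
    return (1.0 - (absorbances.a1 - absorbances.a2) / denom) * 100.0


def cell_viability(absorbances: ViabilityAbsorbances) -> float:
    """Percent cell survival, (As − Ab)/(Ac − Ab)·100."""
    denom = absorbances.a_control - absorbances.a_blank
    if denom == 0:
        raise InvariantError(
            "cell_viability: control pair Ac - Ab is zero; viability undefined"
        )
    return (absorbances.a_sample - absorbances.a_blank) / denom * 100.0


@dataclass(frozen=True)
class IC50Result:
    ic50: float  # μg/mL
    method: str  # "linear_interpolation" | "four_parameter_logistic"
    fit_quality: float  # R² (4PL) or the local slope magnitude (interpolation)
    ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.ic50 <= 0:
            raise InvariantError("IC50Result: ic50 must be positive")
        if self.ci is not None and not (self.ci[0] <= self.ic50 <= self.ci[1]):
            raise InvariantError("IC50Result: ci must bracket ic50")


def _ic50_interpolate(series: DoseResponseSeries) -> IC50Result:
    c = np.asarray(series.concentrations, float)
    y = np.asarray(series.inhibition, float)
    exact = np.nonzero(y == 50.0)[0]
    if exact.size:
        i = int(exact[0])
        slope = np.inf if c.size == 1 else float(np.gradient(y, c)[i])
        return IC50Result(float(c[i]), "linear_interpolation", abs(slope))
    for i in range(c.size - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - 50.0) * (y1 - 50.0) < 0:
            frac = (50.0 - y0) / (y1 - y0)
            return IC50Result(
                float(c[i] + frac * (c[i + 1] - c[i])),
                "linear_interpolation",
                abs(float((y1 - y0) / (c[i + 1] - c[i]))),
            )
    raise BracketingError(
        "estimate_ic50: no adjacent pair of points brackets 50% inhibition"
    )


def _four_pl(x, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (ic50 / np.maximum(x, 1e-300)) ** hill)


def _ic50_logistic(series: DoseResponseSeries) -> IC50Result:
    c = np.asarray(series.concentrations, float)
    y = np.asarray(series.inhibition, float)
    p0 = (float(y.min()), float(y.max()), float(np.median(c[c > 0])) or 1.0, 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            _four_pl, c, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12, 1e-3], [np.inf, np.inf, np.inf, 100.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    resid = y - _four_pl(c, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    ic50 = float(popt[2])
    se = float(np.sqrt(np.diag(pcov))[2])
    ci = None
    if np.isfinite(se) and ic50 - 1.96 * se > 0:
        ci = (ic50 - 1.96 * se, ic50 + 1.96 * se)
    return IC50Result(ic50, "four_parameter_logistic", r2, ci)


def estimate_ic50(
    series: DoseResponseSeries, method: str = "linear_interpolation"
) -> IC50Result:
    """Half-maximal inhibitory concentration from a dose-response series.

    'linear_interpolation' locates the first adjacent pair bracketing 50%
    and interpolates linearly (assumption-free); 'four_parameter_logistic'
    fits the 4PL curve and reports its midpoint.
    """
    if len(series.concentrations) < 4:
        raise InvariantError("estimate_ic50: need >= 4 dose-response points")
    if method == "linear_interpolation":
        return _ic50_interpolate(series)
    if method == "four_parameter_logistic":
        return _ic50_logistic(series)
    raise InvariantError(f"estimate_ic50: unknown method {method!r}")


@dataclass(frozen=True)
class ReversibilityVerdict:
    """Outcome of the enzyme-dilution reversibility test.

    A reversible inhibitor yields velocity-vs-enzyme lines through the
    origin whose slopes fall strictly as inhibitor concentration rises;
    ``flags`` names each violated condition.
    """

    reversible: bool
    slopes: tuple[float, ...]  # ordered by inhibitor concentration
    intercepts: tuple[float, ...]
    flags: tuple[str, ...]


def reversibility_verdict(
    lines: list[ReversibilitySeries], origin_tolerance: float = 0.05
) -> ReversibilityVerdict:
    """Fit v = a + b·[E] per inhibitor level and test origin intersection
    plus slope monotonicity.

    ``origin_tolerance`` is the admissible |intercept| as a fraction of the
    largest measured velocity.
    """
    if len(lines) < 2:
        raise InvariantError("reversibility_verdict: need >= 2 inhibitor levels")
    lines = sorted(lines, key=lambda s: s.inhibitor_conc)
    vmax_all = max(max(s.velocity) for s in lines)
    slopes, intercepts = [], []
    for s in lines:
        e = np.asarray(s.enzyme_activity, float)
        if np.unique(e).size < 2:
            raise FitError(
                f"reversibility line at [I]={s.inhibitor_conc} is rank-deficient "
                "(all enzyme activities equal)"
            )
        res = stats.linregress(e, np.asarray(s.velocity, float))
        slopes.append(float(res.slope))
        intercepts.append(float(res.intercept))
    flags = []
    if any(abs(a) > origin_tolerance * vmax_all for a in intercepts):
        flags.append("not_through_origin")
    if not all(b1 > b2 for b1, b2 in zip(slopes, slopes[1:])):
        flags.append("slopes_not_strictly_decreasing")
    return ReversibilityVerdict(
        reversible=not flags,
        slopes=tuple(slopes),
        intercepts=tuple(intercepts),
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class StabilityProfile:
    """Per-condition inhibition rates with a flatness summary."""

    rates: dict[str, float]  # condition label -> percent inhibition
    rate_range: float  # max - min
    max_condition: str


def stability_profile(grid: dict[str, AssayAbsorbances]) -> StabilityProfile:
    """Inhibition rate across a temperature or pH condition grid."""
    if len(grid) < 2:
        raise InvariantError("stability_profile: need >= 2 conditions")
    rates = {cond: inhibition_rate(a) for cond, a in grid.items()}
    values = list(rates.values())
    max_condition = max(rates, key=lambda k: rates[k])
    return StabilityProfile(
        rates=rates,
        rate_range=float(max(values) - min(values)),
        max_condition=max_condition,
    )
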