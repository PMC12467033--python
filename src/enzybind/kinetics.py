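"""Inhibition kinetics: Michaelis-Menten fits per inhibitor level, inhibition
type classification and secondary-plot inhibition constants.

The workflow mirrors the classical double-reciprocal analysis: each
substrate-velocity series at inhibitor concentration [I] is fitted to
v = Vmax·[S]/(Km + [S]) (directly, or through the Lineweaver-Burk
linearization 1/v = (Km/Vmax)·1/[S] + 1/Vmax), the trends in apparent Km and
Vmax over [I] diagnose the inhibition type, and the secondary regressions

    slope([I])       = Km/Vmax + Km·[I]/(Vmax·Ki)
    y-intercept([I]) = 1/Vmax + [I]/(Vmax·Kis)

yield the free-enzyme constant Ki and the enzyme-substrate-complex constant
Kis as intercept/slope of each secondary line.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import optimize, stats

from .datatypes import KineticSeries
from .errors import FitError, InvariantError, NotApplicableError

INHIBITION_TYPES = ("competitive", "noncompetitive", "uncompetitive", "mixed")


@dataclass(frozen=True)
class KineticFit:
    """Apparent Michaelis-Menten parameters at one inhibitor concentration."""

    km: float  # mmol/L
    vmax: float  # ΔOD/min
    se_km: float
    se_vmax: float
    inhibitor_conc: float
    r_squared: float

    def __post_init__(self):
        if self.km <= 0 or self.vmax <= 0:
            raise InvariantError("KineticFit: Km and Vmax must be positive")

    @property
    def lb_slope(self) -> float:
        """Lineweaver-Burk slope Km/Vmax."""
        return self.km / self.vmax

    @property
    def lb_intercept(self) -> float:
        """Lineweaver-Burk y-intercept 1/Vmax."""
        return 1.0 / self.vmax

    @classmethod
    def from_constants(
        cls, km: float, vmax: float, inhibitor_conc: float = 0.0
    ) -> "KineticFit":
        """Wrap already-known apparent constants (e.g. from a published table)."""
        return cls(
            km=km,
            vmax=vmax,
            se_km=float("nan"),
            se_vmax=float("nan"),
            inhibitor_conc=inhibitor_conc,
            r_squared=float("nan"),
        )


@dataclass(frozen=True)
class SecondaryFit:
    """Diagnostics of one secondary OLS regression on [I]."""

    slope: float
    intercept: float
    r_squared: float
    se_slope: float
    se_intercept: float


@dataclass(frozen=True)
class KiEstimate:
    value: float  # μg/mL
    regression: SecondaryFit


@dataclass(frozen=True)
class InhibitionClassification:
    """Type verdict with the two independent lines of evidence.

    ``trend_signal`` comes from how apparent Km/Vmax move with [I];
    ``geometry_signal`` from where the Lineweaver-Burk lines intersect.  When
    both are defined and disagree the verdict is 'ambiguous' rather than a
    silent choice.
    """

    inhibition_type: str  # one of INHIBITION_TYPES or "ambiguous"
    trend_signal: str | None
    geometry_signal: str | None
    km_relative_spread: float
    vmax_relative_spread: float
    intersection: tuple[float, float] | None  # centroid of pairwise crossings
    intersection_dispersion: float | None
    quadrant: str | None


def fit_kinetics(series: KineticSeries, mode: str = "lineweaver_burk") -> KineticFit:
    """Fit apparent Km and Vmax for one inhibitor level.

    'lineweaver_burk' regresses 1/v on 1/[S] by ordinary least squares and
    maps (slope, intercept) -> (Km, Vmax) = (slope/intercept, 1/intercept);
    'nonlinear' fits v = Vmax·[S]/(Km+[S]) directly by least squares.
    """
    s = np.asarray(series.substrate, float)
    v = np.asarray(series.velocity, float)
    if mode == "lineweaver_burk":
        res = stats.linregress(1.0 / s, 1.0 / v)
        if res.intercept <= 0:
            raise FitError(
                "Lineweaver-Burk intercept is non-positive; fit is ill-conditioned"
            )
        if res.slope <= 0:
            raise FitError("Lineweaver-Burk slope is non-positive")
        vmax = 1.0 / res.intercept
        km = res.slope / res.intercept
        # delta-method propagation (covariance between slope and intercept
        # ignored; adequate as a reporting-scale uncertainty)
        se_vmax = res.intercept_stderr / res.intercept**2
        se_km = km * float(
            np.hypot(
                res.stderr / res.slope, res.intercept_stderr / res.intercept
            )
        )
        return KineticFit(
            km=km,
            vmax=vmax,
            se_km=se_km,
            se_vmax=se_vmax,
            inhibitor_conc=series.inhibitor_conc,
            r_squared=float(res.rvalue**2),
        )
    if mode == "nonlinear":
        p0 = (float(np.median(s)), float(v.max()))

        def mm(x, km, vmax):
            return vmax * x / (km + x)

        try:
            popt, pcov = optimize.curve_fit(
                mm, s, v, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
        km, vmax = popt
        se = np.sqrt(np.diag(pcov))
        resid = v - mm(s, *popt)
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return KineticFit(
            km=float(km),
            vmax=float(vmax),
            se_km=float(se[0]),
            se_vmax=float(se[1]),
            inhibitor_conc=series.inhibitor_conc,
            r_squared=r2,
        )
    raise InvariantError(f"unknown kinetics fitting mode {mode!r}")


def _sorted_fits(fits: list[KineticFit]) -> list[KineticFit]:
    fits = sorted(fits, key=lambda f: f.inhibitor_conc)
    if len(fits) < 3:
        raise InvariantError("need >= 3 inhibitor concentrations")
    if fits[0].inhibitor_conc != 0:
        raise InvariantError("the [I] = 0 reference fit is required")
    return fits


def _geometry(fits: list[KineticFit], tol: float):
    """Centroid of pairwise Lineweaver-Burk line intersections and its
    quadrant label."""
    slopes = np.array([f.lb_slope for f in fits])
    intercepts = np.array([f.lb_intercept for f in fits])
    slope_spread = (slopes.max() - slopes.min()) / slopes.mean()
    if slope_spread <= tol:
        return None, None, "parallel"
    pts = []
    for i, j in combinations(range(len(fits)), 2):
        ds = slopes[i] - slopes[j]
        if abs(ds) < 1e-12 * max(abs(slopes[i]), abs(slopes[j])):
            continue
        x = (intercepts[j] - intercepts[i]) / ds
        pts.append((x, intercepts[i] + slopes[i] * x))
    if not pts:
        return None, None, "parallel"
    pts = np.asarray(pts)
    cx, cy = pts.mean(axis=0)
    dispersion = float(np.hypot(*pts.std(axis=0)))
    y_scale = float(intercepts.mean())  # characteristic 1/Vmax
    x_scale = float(np.mean(intercepts / slopes))  # characteristic 1/Km
    if abs(cx) <= tol * x_scale:
        quadrant = "y_axis"
    elif cx < 0 and abs(cy) <= tol * y_scale:
        quadrant = "negative_x_axis"
    elif cx < 0 and cy > 0:
        quadrant = "second_quadrant"
    elif cx < 0:
        quadrant = "third_quadrant"
    else:
        quadrant = "right_half_plane"
    return (float(cx), float(cy)), dispersion, quadrant


_GEOMETRY_TYPE = {
    "second_quadrant": "mixed",
    "negative_x_axis": "noncompetitive",
    "y_axis": "competitive",
    "parallel": "uncompetitive",
}


def classify_inhibition(
    fits: list[KineticFit], tol: float = 0.05
) -> InhibitionClassification:
    """Classify the inhibition type from apparent-constant trends and
    Lineweaver-Burk geometry.

    Trend rules (spreads relative to the [I] = 0 value, tolerance ``tol``):
    Km unchanged and Vmax strictly falling -> noncompetitive; Km rising and
    Vmax falling -> mixed; Vmax unchanged and Km rising -> competitive; both
    falling -> uncompetitive.  The pairwise intersection centroid of the
    Lineweaver-Burk lines provides an independent geometric signal; a
    disagreement between the two yields 'ambiguous' with both signals kept.
    """
    fits = _sorted_fits(fits)
    km = np.array([f.km for f in fits])
    vmax = np.array([f.vmax for f in fits])
    km_spread = float((km.max() - km.min()) / km[0])
    vmax_spread = float((vmax.max() - vmax.min()) / vmax[0])
    km_const = km_spread <= tol
    vmax_const = vmax_spread <= tol
    km_rising = bool(np.all(np.diff(km) > 0))
    km_falling = bool(np.all(np.diff(km) < 0))
    vmax_falling = bool(np.all(np.diff(vmax) < 0))

    if km_const and vmax_falling:
        trend = "noncompetitive"
    elif vmax_const and km_rising:
        trend = "competitive"
    elif km_rising and vmax_falling:
        trend = "mixed"
    elif km_falling and vmax_falling:
        trend = "uncompetitive"
    else:
        trend = None

    centroid, dispersion, quadrant = _geometry(fits, tol)
    geometry = _GEOMETRY_TYPE.get(quadrant)

    if trend is not None and (geometry is None or geometry == trend):
        verdict = trend
    elif trend is None and geometry is not None:
        verdict = geometry
    else:
        verdict = "ambiguous"
    return InhibitionClassification(
        inhibition_type=verdict,
        trend_signal=trend,
        geometry_signal=geometry,
        km_relative_spread=km_spread,
        vmax_relative_spread=vmax_spread,
        intersection=centroid,
        intersection_dispersion=dispersion,
        quadrant=quadrant,
    )


def _secondary_ols(x: np.ndarray, y: np.ndarray) -> SecondaryFit:
    res = stats.linregress(x, y)
    return SecondaryFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
    )


def estimate_ki(fits: list[KineticFit]) -> KiEstimate:
    """Free-enzyme inhibition constant from the slope secondary plot.

    Regresses the Lineweaver-Burk slope Km_app/Vmax_app on [I]; the model
    slope([I]) = Km/Vmax · (1 + [I]/Ki) gives Ki = intercept/slope of the
    secondary line.
    """
    fits = _sorted_fits(fits)
    conc = np.array([f.inhibitor_conc for f in fits])
    reg = _secondary_ols(conc, np.array([f.lb_slope for f in fits]))
    if reg.slope <= 0:
        raise FitError(
            "secondary slope regression is non-increasing: no inhibition signal"
        )
    return KiEstimate(value=reg.intercept / reg.slope, regression=reg)


def estimate_kis(
    fits: list[KineticFit], inhibition_type: str = "mixed"
) -> KiEstimate:
    """Enzyme-substrate-complex inhibition constant from the intercept
    secondary plot (1/Vmax_app vs [I]); defined for mixed (and uncompetitive
    contexts) only."""
    if inhibition_type in ("noncompetitive", "competitive"):
        raise NotApplicableError(
            f"Kis is not defined for {inhibition_type} inhibition"
        )
    fits = _sorted_fits(fits)
    conc = np.array([f.inhibitor_conc for f in fits])
    reg = _secondary_ols(conc, np.array([f.lb_intercept for f in fits]))
    if reg.slope <= 0:
        raise FitError(
            "secondary intercept regression is non-increasing: no inhibition signal"
        )
    return KiEstimate(value=reg.intercept / reg.slope, regression=reg)
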