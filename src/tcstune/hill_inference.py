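"""Hill transfer-function inference with inverse-mean weighting and
profile F-test confidence intervals.

Dose-response data (inducer concentration in uM vs. fluorescence in MEFL,
replicates pooled across days) are fit to the activating Hill equation

    y = low + (high - low) * x^n / (K_1/2^n + x^n)

by weighted nonlinear least squares: each residual is divided by the mean
observed response at its dose, so that the low and high plateaus are fit
on comparable relative scales.  95% confidence intervals per parameter
come from profiling: the parameter is fixed on an adaptive grid, all
others refit, and the bound is where the F statistic

    F = (rss_fixed - rss_min) / (rss_min / (n_obs - n_params))

crosses the F(1, n_obs - n_params) quantile.  Inversion of a fitted curve
(x = K_1/2 * (r / (1 - r))^(1/n), r = (y - low)/(high - low)) supports the
iso-SK induction design and soil-nitrate reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .tcs_model import TransferCurve

__all__ = [
    "DoseResponse",
    "HillFit",
    "ConfInterval",
    "FoldChangeResult",
    "RangeMetrics",
    "IsoSKDesignRow",
    "SoilReport",
    "FitError",
    "hill_eval",
    "fit_hill",
    "ci_f_test",
    "hill_invert",
    "fold_change",
    "range_metrics",
    "design_isosk_inductions",
    "report_soil_concentration",
]

PARAM_NAMES = ("low", "high", "k_half", "n")


class FitError(RuntimeError):
    """Fit refused (degenerate data) or failed to converge."""


@dataclass
class DoseResponse:
    """Pooled dose-response records: dose (uM), response (MEFL), replicate label."""

    doses: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.replicates = np.asarray(self.replicates)
        if not (len(self.doses) == len(self.responses) == len(self.replicates)):
            raise ValueError("doses, responses and replicates must have equal length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")
        if np.any(~np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    def n_distinct_doses(self) -> int:
        return len(np.unique(self.doses))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_uM": self.doses,
            "response_mefl": self.responses,
            "replicate": self.replicates,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **metadata) -> "DoseResponse":
        return cls(df["dose_uM"].to_numpy(), df["response_mefl"].to_numpy(),
                   df["replicate"].to_numpy(), metadata=metadata)

    @classmethod
    def read_csv(cls, path) -> "DoseResponse":
        return cls.from_frame(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ConfInterval:
    """A (lower, upper) confidence bound, unpackable as a 2-tuple.

    ``lower_unbounded``/``upper_unbounded`` flag bounds that never crossed
    the F threshold inside the search range (reported as the range end —
    e.g. a K_1/2 interval printed as "0-23 uM").
    """

    lower: float
    upper: float
    lower_unbounded: bool = False
    upper_unbounded: bool = False

    def __iter__(self):
        yield self.lower
        yield self.upper

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class HillFit:
    """Fitted activating-Hill parameters with diagnostics."""

    low: float
    high: float
    k_half: float
    n: float
    rss: float = np.nan
    n_obs: int = 0
    n_params: int = 4
    ci95: dict = field(default_factory=dict)   # name -> ConfInterval

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ValueError("require high >= low")
        if self.k_half <= 0 or self.n <= 0:
            raise ValueError("require k_half > 0 and n > 0")

    def eval(self, x) -> np.ndarray | float:
        return hill_eval(x, self.low, self.high, self.k_half, self.n)

    def params_dict(self) -> dict:
        return {"low": self.low, "high": self.high,
                "k_half": self.k_half, "n": self.n}

    def to_json(self, path=None) -> str:
        d = {**self.params_dict(), "rss": self.rss, "n_obs": self.n_obs,
             "n_params": self.n_params,
             "ci95": {k: [v.lower, v.upper] for k, v in self.ci95.items()}}
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "HillFit":
        with open(path) as fh:
            d = json.load(fh)
        ci = {k: ConfInterval(*v) for k, v in d.pop("ci95", {}).items()}
        return cls(low=d["low"], high=d["high"], k_half=d["k_half"], n=d["n"],
                   rss=d.get("rss", np.nan), n_obs=d.get("n_obs", 0),
                   n_params=d.get("n_params", 4), ci95=ci)


def hill_eval(x, low: float, high: float, k_half: float, n: float):
    """Activating Hill: y = low + (high - low) x^n / (K^n + x^n); exact at x=0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        xn = np.where(x > 0, x, 1.0) ** n
        frac = np.where(x > 0, xn / (k_half ** n + xn), 0.0)
    out = low + (high - low) * frac
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _dose_mean_weights(data: DoseResponse, weight_floor: float) -> np.ndarray:
    """Per-point weight denominator: mean response at that dose, floored.

    The floor (default 1 MEFL, or the LOD when the caller knows it) guards
    against non-positive means after autofluorescence subtraction.
    """
    means = pd.Series(data.responses).groupby(pd.Series(data.doses)).transform("mean")
    return np.maximum(means.to_numpy(), weight_floor)


def weighted_rss(data: DoseResponse, fit: HillFit | dict,
                 weight_floor: float = 1.0) -> float:
    """Independent recomputation of sum(((y - yhat) / mean(y at dose))^2)."""
    p = fit.params_dict() if isinstance(fit, HillFit) else fit
    m = _dose_mean_weights(data, weight_floor)
    resid = (data.responses - hill_eval(data.doses, **p)) / m
    return float(np.sum(resid ** 2))


def _make_params(data: DoseResponse) -> lmfit.Parameters:
    by_dose = pd.Series(data.responses).groupby(pd.Series(data.doses)).mean()
    lo0, hi0 = float(by_dose.min()), float(by_dose.max())
    pos = data.doses[data.doses > 0]
    k0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
    p = lmfit.Parameters()
    p.add("low", value=max(lo0, 0.0), min=0.0)
    p.add("high", value=max(hi0, 1e-12), min=0.0)
    p.add("k_half", value=k0, min=1e-12)
    p.add("n", value=1.0, min=0.1, max=10.0)
    return p


def _residual(params: lmfit.Parameters, x: np.ndarray, y: np.ndarray,
              m: np.ndarray) -> np.ndarray:
    yhat = hill_eval(x, params["low"].value, params["high"].value,
                     params["k_half"].value, params["n"].value)
    return (y - yhat) / m


def _minimize(params: lmfit.Parameters, data: DoseResponse,
              m: np.ndarray) -> lmfit.minimizer.MinimizerResult:
    return lmfit.minimize(
        _residual, params, args=(data.doses, data.responses, m),
        method="leastsq", xtol=1e-13, ftol=1e-13, max_nfev=20000,
    )


def fit_hill(
    data: DoseResponse,
    compute_ci: bool = True,
    ci_level: float = 0.95,
    ci_params: Sequence[str] = PARAM_NAMES,
    weight_floor: float = 1.0,
) -> HillFit:
    """Fit the activating Hill equation with inverse-mean weighting.

    Requires >= 4 distinct dose levels and non-constant responses.  The
    solver is restarted once from its own solution; the restart never
    increases the weighted RSS.  Set ``compute_ci=False`` to skip the
    (comparatively expensive) profile confidence intervals.
    """
    if data.n_distinct_doses() < 4:
        raise FitError(
            f"need >= 4 distinct doses, got {data.n_distinct_doses()}")
    if np.allclose(data.responses, data.responses[0]):
        raise FitError("degenerate data: all responses equal")
    m = _dose_mean_weights(data, weight_floor)
    params = _make_params(data)
    try:
        res = _minimize(params, data, m)
        res2 = _minimize(res.params, data, m)  # polish from the solution
    except Exception as exc:  # pragma: no cover - lmfit internal failures
        raise FitError(
            f"minimization failed from starting point "
            f"{ {k: v.value for k, v in params.items()} }: {exc}") from exc
    best = min((res, res2), key=lambda r: float(np.sum(r.residual ** 2)))
    vals = {k: float(best.params[k].value) for k in PARAM_NAMES}
    fit = HillFit(**vals, rss=float(np.sum(best.residual ** 2)),
                  n_obs=len(data.responses), n_params=len(PARAM_NAMES))
    if compute_ci:
        fit.ci95 = {p: ci_f_test(fit, data, p, level=ci_level,
                                 weight_floor=weight_floor)
                    for p in ci_params}
    return fit


def _rss_fixed(data: DoseResponse, m: np.ndarray, fit: HillFit,
               param: str, value: float) -> float:
    """Refit all parameters except ``param`` fixed at ``value``; return RSS."""
    params = _make_params(data)
    for k in PARAM_NAMES:  # warm-start from the unconstrained optimum
        params[k].value = getattr(fit, k)
    # keep the fixed value inside the variable's bounds
    params[param].set(value=value, vary=False, min=-np.inf
                      if param in ("low", "high") else 1e-300, max=np.inf)
    if param == "n":
        params["n"].set(min=min(0.1, value), max=max(10.0, value))
    res = _minimize(params, data, m)
    return float(np.sum(res.residual ** 2))


def ci_f_test(
    fit: HillFit,
    data: DoseResponse,
    param: str,
    level: float = 0.95,
    weight_floor: float = 1.0,
    max_steps: int = 50,
) -> ConfInterval:
    """Profile F-test confidence interval for one Hill parameter.

    The parameter is stepped away from its estimate (multiplicatively for
    k_half and n, additively for low/high), all other parameters refit at
    each step, and the bound interpolated where the excess-RSS F statistic
    crosses the F(1, dof) quantile.  A side that never crosses within
    ``max_steps`` refits is reported at the search-range end and flagged
    unbounded; negative concentrations are never reported (a non-crossing
    lower bound for k_half is floored at 0).
    """
    if param not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {param!r}; expected one of {PARAM_NAMES}")
    dof = fit.n_obs - fit.n_params
    if dof <= 0:
        raise FitError("no residual degrees of freedom for an F-test interval")
    m = _dose_mean_weights(data, weight_floor)
    rss_min = max(fit.rss, 1e-30)  # machine-epsilon floor for exact fits
    fq = f_dist.ppf(level, 1, dof)
    rss_target = rss_min * (1.0 + fq / dof)
    est = getattr(fit, param)
    multiplicative = param in ("k_half", "n")
    amp_step = 0.05 * max(fit.high - fit.low, abs(est), 1e-12)

    def profile(direction: int) -> tuple[float, bool]:
        prev_v, prev_rss = est, rss_min
        step = 0.1 if multiplicative else amp_step
        for i in range(max_steps):
            if multiplicative:
                v = est * (1.0 + step) ** (i + 1) if direction > 0 \
                    else est / (1.0 + step) ** (i + 1)
            else:
                v = est + direction * step * (i + 1) ** 1.5
            if param in ("low", "high", "k_half") and v < 0:
                v = 0.0
            rss_v = _rss_fixed(data, m, fit, param, max(v, 1e-300)
                               if param in ("k_half", "n") else v)
            if rss_v >= rss_target:
                # linear interpolation in RSS between the last two profile points
                if rss_v == prev_rss:
                    return v, False
                t = (rss_target - prev_rss) / (rss_v - prev_rss)
                return prev_v + t * (v - prev_v), False
            prev_v, prev_rss = v, rss_v
            if v == 0.0:
                break
        # never crossed: unbounded within the search range
        end = 0.0 if (direction < 0 and param in ("low", "k_half", "n")) else prev_v
        return end, True

    lo, lo_unb = profile(-1)
    hi, hi_unb = profile(+1)
    lo = min(lo, est)
    hi = max(hi, est)
    return ConfInterval(lo, hi, lo_unb, hi_unb)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def hill_invert(fit: HillFit, y: float) -> float:
    """Inducer concentration producing response ``y`` under the fit.

    x = K_1/2 * (r / (1 - r))^(1/n) with r = (y - low)/(high - low);
    defined only on the open response interval (low, high).
    """
    if not (fit.low < y < fit.high):
        raise ValueError(
            f"response {y} outside the fit's open range ({fit.low}, {fit.high})")
    r = (y - fit.low) / (fit.high - fit.low)
    return float(fit.k_half * (r / (1.0 - r)) ** (1.0 / fit.n))


@dataclass(frozen=True)
class FoldChangeResult:
    value: float
    is_lower_bound: bool


def fold_change(induced: float, uninduced: float, lod: float) -> FoldChangeResult:
    """Induced/uninduced ratio of autofluorescence-subtracted sfGFP.

    Any input below the limit of detection (LOD = 3 * sigma of
    autofluorescence) is replaced by the LOD; the result is then a lower
    bound on the true fold change and flagged as such.
    """
    if lod <= 0:
        raise ValueError("lod must be > 0")
    sub = False
    if induced < lod:
        induced, sub = lod, True
    if uninduced < lod:
        uninduced, sub = lod, True
    return FoldChangeResult(value=induced / uninduced, is_lower_bound=sub)


@dataclass(frozen=True)
class RangeMetrics:
    dynamic_range: float
    amplitude_range: float
    floored: bool = False  # dynamic range computed against an LOD floor


def range_metrics(fit_or_curve: HillFit | TransferCurve,
                  lod: float | None = None) -> RangeMetrics:
    """Dynamic range (high/low) and amplitude range (high - low).

    For a :class:`TransferCurve`, high/low are the max/min outputs.  A
    non-positive low is floored at ``lod`` (flagged) for the ratio.
    """
    if isinstance(fit_or_curve, HillFit):
        lo, hi = fit_or_curve.low, fit_or_curve.high
    else:
        if len(fit_or_curve) == 0:
            raise ValueError("empty curve")
        lo, hi = float(fit_or_curve.outputs.min()), float(fit_or_curve.outputs.max())
    amplitude = hi - lo
    if lo > 0:
        return RangeMetrics(hi / lo, amplitude)
    if lod is not None and lod > 0:
        return RangeMetrics(hi / lod, amplitude, floored=True)
    return RangeMetrics(np.inf if hi > 0 else 1.0, amplitude, floored=True)


@dataclass(frozen=True)
class IsoSKDesignRow:
    inducer1: float
    inducer2: float
    fraction: float


def _invert_or_zero(fit: HillFit, target: float, which: str) -> float:
    tol = 1e-9 * max(abs(fit.low), 1.0)
    if target <= fit.low + tol:
        return 0.0
    if target >= fit.high:
        raise ValueError(
            f"target {target} MEFL unreachable for {which}: achievable window "
            f"is [{fit.low}, {fit.high}) MEFL")
    return hill_invert(fit, target)


def design_isosk_inductions(
    fit_inducer1: HillFit,
    fit_inducer2: HillFit,
    total_target: float,
    fractions: Iterable[float],
) -> list[IsoSKDesignRow]:
    """Inducer pairs holding total SK expression at ``total_target`` MEFL
    while varying the wild-type fraction.

    For each fraction f, pool 1 is induced to f*total and pool 2 to
    (1-f)*total by inverting the two inducer->SK-expression Hill fits; a
    target at or below a fit's basal level maps to inducer 0.
    """
    rows = []
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
        i1 = _invert_or_zero(fit_inducer1, f * total_target, "inducer 1")
        i2 = _invert_or_zero(fit_inducer2, (1.0 - f) * total_target, "inducer 2")
        rows.append(IsoSKDesignRow(i1, i2, float(f)))
    return rows


@dataclass(frozen=True)
class SoilReport:
    reported: float | None
    status: Literal["ok", "below_detection", "saturated"]
    within_twofold: bool | None = None


def report_soil_concentration(
    standard: HillFit,
    fluorescence: float,
    true_value: float | None = None,
) -> SoilReport:
    """Bacterially reported nitrate concentration from a fluorescence reading.

    Inverts the previously measured standard curve; readings at or below
    the standard's low plateau return a below-detection status, at or above
    the high plateau a saturated status (no extrapolation).  When the true
    spike is known, flags whether the report is within twofold of it.
    """
    if fluorescence <= standard.low:
        return SoilReport(None, "below_detection")
    if fluorescence >= standard.high:
        return SoilReport(None, "saturated")
    reported = hill_invert(standard, fluorescence)
    within = None
    if true_value is not None:
        if true_value <= 0:
            raise ValueError("true_value must be > 0")
        within = 0.5 <= reported / true_value <= 2.0
    return SoilReport(reported, "ok", within)
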