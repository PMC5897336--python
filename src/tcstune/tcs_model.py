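"""Mechanistic steady-state model of a bifunctional two-component system.

A sensor histidine kinase (SK) autophosphorylates in response to an input
ligand and transfers the phosphoryl group to a shared response regulator
(RR); the bifunctional SK also dephosphorylates RR~P. The model is the
two-ODE mass-action reduction

    d[SK~P]/dt = kappa * k_auto(I) * (SK_tot - SK~P)
                 - k_transfer * SK~P * (RR_tot - RR~P)
    d[RR~P]/dt = k_transfer * SK~P * (RR_tot - RR~P)
                 - phi * k_phos(I) * (SK_tot - SK~P) * RR~P
                 - k_dephos_bg * RR~P

where the autophosphorylation rate k_auto(I) rises and the phosphatase
rate k_phos(I) falls along a Hill function of the input I (input coupling
can be restricted to either arm).  ``kappa`` and ``phi`` are dimensionless
scale factors on the kinase and phosphatase activities (1 = wild type);
sweeping them predicts how the detection threshold K_1/2 — the input at
which promoter output is half-maximal — shifts with kinase/phosphatase
balance.  Transcriptional output is a Hill function of [RR~P] through a
:class:`PromoterModel`.

Steady states are found by reducing the two-variable system to a scalar
root problem in [RR~P] (the SK~P nullcline gives SK~P in closed form) and
bracketing on [0, RR_tot]; a long-time ODE integration is available as an
independent check (:func:`integrate_to_steady_state`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "TCSParameters",
    "PromoterModel",
    "TransferCurve",
    "SweepRow",
    "SweepResult",
    "SteadyStateError",
    "ThresholdError",
    "steady_state",
    "integrate_to_steady_state",
    "simulate_transfer_function",
    "k_half_of_curve",
    "sweep_activity",
    "isosk_transfer",
    "default_parameters",
    "default_promoter",
    "default_input_grid",
]

#: absolute bound on both ODE right-hand sides at an accepted steady state
RESIDUAL_TOL = 1e-9

InputCoupling = Literal["dual", "kinase", "phosphatase"]


class SteadyStateError(RuntimeError):
    """Raised when no steady state satisfying the residual tolerance is found."""


class ThresholdError(ValueError):
    """Raised when K_1/2 is undefined (flat curve) or not bracketed by the grid."""


@dataclass(frozen=True)
class TCSParameters:
    """Kinetic constants, protein totals, and activity scale factors.

    Units: concentrations in uM, first-order rates in 1/s, bimolecular
    rates in 1/(uM*s).  ``kappa`` scales kinase (autophosphorylation)
    activity, ``phi`` scales phosphatase activity; both are 1 for wild
    type.  ``coupling`` selects which catalytic arm the input modulates:
    "dual" (default; input both raises k_auto and lowers k_phos),
    "kinase" (k_phos pinned at k_phos_max) or "phosphatase" (k_auto
    pinned at k_auto_max, i.e. a constitutively active kinase).
    """

    sk_tot: float = 1.0
    rr_tot: float = 10.0
    k_auto_basal: float = 0.01
    k_auto_max: float = 1.0
    k_input_half: float = 10.0
    h_input: float = 1.0
    k_transfer: float = 1.0
    k_phos_max: float = 0.5
    k_phos_min: float = 0.05
    k_dephos_bg: float = 1e-3
    kappa: float = 1.0
    phi: float = 1.0
    coupling: InputCoupling = "dual"

    def __post_init__(self) -> None:
        for name in (
            "sk_tot", "rr_tot", "k_auto_basal", "k_auto_max", "k_input_half",
            "h_input", "k_transfer", "k_phos_max", "k_phos_min",
            "k_dephos_bg", "kappa", "phi",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.k_auto_max < self.k_auto_basal:
            raise ValueError("k_auto_max must be >= k_auto_basal")
        if self.k_phos_max < self.k_phos_min:
            raise ValueError("k_phos_max must be >= k_phos_min")
        if self.coupling not in ("dual", "kinase", "phosphatase"):
            raise ValueError(f"unknown coupling {self.coupling!r}")

    def _occupancy(self, inp: float) -> float:
        """Hill occupancy of the input-binding site, in [0, 1]."""
        if inp < 0:
            raise ValueError(f"input must be >= 0, got {inp}")
        if inp == 0:
            return 0.0
        kh = self.k_input_half
        if kh == 0:
            return 1.0
        r = (inp / kh) ** self.h_input
        return r / (1.0 + r)

    def k_auto(self, inp: float) -> float:
        """Autophosphorylation rate at input ``inp`` (before kappa scaling)."""
        if self.coupling == "phosphatase":
            return self.k_auto_max
        u = self._occupancy(inp)
        return self.k_auto_basal + (self.k_auto_max - self.k_auto_basal) * u

    def k_phos(self, inp: float) -> float:
        """SK-catalysed RR~P dephosphorylation rate at ``inp`` (before phi)."""
        if self.coupling == "kinase":
            return self.k_phos_max
        u = self._occupancy(inp)
        return self.k_phos_max - (self.k_phos_max - self.k_phos_min) * u


@dataclass(frozen=True)
class PromoterModel:
    """Hill response of the output promoter to [RR~P].

    ``rrp_half`` is the RR~P concentration giving half-maximal output
    (RR~P_1/2); output units are arbitrary but consistent.
    """

    v_min: float = 1.0
    v_max: float = 1000.0
    rrp_half: float = 1.0
    h_prom: float = 1.5

    def __post_init__(self) -> None:
        if not (self.v_max > self.v_min >= 0):
            raise ValueError("require v_max > v_min >= 0")
        if self.rrp_half <= 0 or self.h_prom <= 0:
            raise ValueError("rrp_half and h_prom must be > 0")

    def output(self, rrp: float | np.ndarray) -> float | np.ndarray:
        rrp = np.asarray(rrp, dtype=float)
        frac = rrp ** self.h_prom / (self.rrp_half ** self.h_prom + rrp ** self.h_prom)
        out = self.v_min + (self.v_max - self.v_min) * frac
        return float(out) if out.ndim == 0 else out


@dataclass
class TransferCurve:
    """Ordered (input concentration, transcriptional output) samples."""

    inputs: np.ndarray
    outputs: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.inputs.shape != self.outputs.shape or self.inputs.ndim != 1:
            raise ValueError("inputs and outputs must be 1-D arrays of equal length")
        if len(self.inputs) and np.any(np.diff(self.inputs) <= 0):
            raise ValueError("inputs must be strictly increasing")
        if np.any(~np.isfinite(self.inputs)) or np.any(~np.isfinite(self.outputs)):
            raise ValueError("curve values must be finite")
        if np.any(self.inputs < 0) or np.any(self.outputs < 0):
            raise ValueError("curve values must be >= 0")

    def __len__(self) -> int:
        return len(self.inputs)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"input_uM": self.inputs, "output": self.outputs})


@dataclass(frozen=True)
class SweepRow:
    scale: float
    k_half: float          # nan when flat
    dynamic_range: float
    amplitude_range: float
    flat: bool = False


@dataclass
class SweepResult:
    which: str
    rows: list[SweepRow]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "scale": r.scale,
                    "k_half_uM": r.k_half,
                    "dynamic_range": r.dynamic_range,
                    "amplitude_range": r.amplitude_range,
                    "flat": r.flat,
                }
                for r in self.rows
            ]
        )


def default_parameters(**overrides) -> TCSParameters:
    """The documented desk-scale default parameter set (see docs/methods.md)."""
    return TCSParameters(**overrides)


def default_promoter(**overrides) -> PromoterModel:
    return PromoterModel(**overrides)


def default_input_grid(
    params: TCSParameters | None = None,
    n: int = 31,
    decades: float = 2.0,
    include_zero: bool = True,
) -> np.ndarray:
    """Log-spaced input grid of ``n`` points spanning ``+-decades`` around
    k_input_half, with an optional zero point prepended (handled separately
    by the threshold interpolation, which never spans it)."""
    k = (params or default_parameters()).k_input_half
    grid = np.logspace(np.log10(k) - decades, np.log10(k) + decades, n)
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

# Internal pool representation for the shared-RR mixture: each SK pool is
# (sk_tot_i, kappa_i * k_auto_i(I), phi_i * k_phos_i(I)).


def _pool_rates(params: TCSParameters, inp: float) -> tuple[float, float, float]:
    return (
        params.sk_tot,
        params.kappa * params.k_auto(inp),
        params.phi * params.k_phos(inp),
    )


def _skp_of_rrp(s_tot: float, a: float, kt: float, r_tot: float, rrp: float) -> float:
    """SK~P on the SK nullcline, given RR~P. Exact: the SK~P balance is then 0."""
    if a == 0.0 or s_tot == 0.0:
        return 0.0
    denom = a + kt * (r_tot - rrp)
    if denom == 0.0:  # kt == 0 or rrp == r_tot with a == 0 handled above
        return s_tot
    return a * s_tot / denom

def _rrp_balance(
    pools: Sequence[tuple[float, float, float]],
    kt: float,
    r_tot: float,
    k_bg: float,
    rrp: float,
) -> float:
    """d[RR~P]/dt with every SK pool on its own nullcline."""
    net = -k_bg * rrp
    for s_tot, a, p in pools:
        skp = _skp_of_rrp(s_tot, a, kt, r_tot, rrp)
        net += kt * skp * (r_tot - rrp) - p * (s_tot - skp) * rrp
    return net


def _solve_pools(
    pools: Sequence[tuple[float, float, float]],
    kt: float,
    r_tot: float,
    k_bg: float,
) -> tuple[list[float], float]:
    """Steady state of the shared-RR system; returns per-pool SK~P and RR~P."""
    if r_tot == 0.0 or all(a == 0.0 or s == 0.0 for s, a, _ in pools):
        # no RR, or no phosphoflux into the system at all
        rrp = 0.0
        if r_tot == 0.0 and kt > 0:
            # SK~P piles up fully when there is nothing to transfer to
            skps = [s if a > 0 else 0.0 for s, a, _ in pools]
        else:
            skps = [_skp_of_rrp(s, a, kt, r_tot, 0.0) for s, a, _ in pools]
        return skps, rrp
    if kt == 0.0:
        # no phosphotransfer: SK pools saturate, RR~P decays to zero
        return [s if a > 0 else 0.0 for s, a, _ in pools], 0.0

    f = lambda rrp: _rrp_balance(pools, kt, r_tot, k_bg, rrp)
    f_hi = f(r_tot)
    if f_hi >= 0.0:
        # no dephosphorylation path can balance the influx: RR fully
        # phosphorylated (e.g. phi = 0 and k_dephos_bg = 0)
        rrp = r_tot
    else:
        rrp = brentq(f, 0.0, r_tot, xtol=1e-15, rtol=8.9e-16, maxiter=200)
        # one guarded Newton polish to push the residual toward machine zero
        eps = max(1e-9 * r_tot, 1e-12)
        deriv = (f(min(rrp + eps, r_tot)) - f(max(rrp - eps, 0.0))) / (2 * eps)
        if deriv != 0.0 and np.isfinite(deriv):
            step = f(rrp) / deriv
            cand = min(max(rrp - step, 0.0), r_tot)
            if abs(f(cand)) < abs(f(rrp)):
                rrp = cand
    skps = [_skp_of_rrp(s, a, kt, r_tot, rrp) for s, a, _ in pools]
    return skps, rrp


def _residuals(
    pools: Sequence[tuple[float, float, float]],
    kt: float,
    r_tot: float,
    k_bg: float,
    skps: Sequence[float],
    rrp: float,
) -> list[float]:
    res = []
    net = -k_bg * rrp
    for (s_tot, a, p), skp in zip(pools, skps):
        res.append(a * (s_tot - skp) - kt * skp * (r_tot - rrp))
        net += kt * skp * (r_tot - rrp) - p * (s_tot - skp) * rrp
    res.append(net)
    return res


def steady_state(params: TCSParameters, inp: float) -> tuple[float, float]:
    """Steady state (SK~P, RR~P) of the two-ODE model at input ``inp`` (uM).

    Raises :class:`SteadyStateError` if the residual tolerance (1e-9 on both
    right-hand sides) cannot be met, and ``ValueError`` for negative input.
    """
    if inp < 0:
        raise ValueError(f"input must be >= 0, got {inp}")
    pool = _pool_rates(params, inp)
    skps, rrp = _solve_pools([pool], params.k_transfer, params.rr_tot,
                             params.k_dephos_bg)
    res = _residuals([pool], params.k_transfer, params.rr_tot,
                     params.k_dephos_bg, skps, rrp)
    if max(abs(r) for r in res) > RESIDUAL_TOL:
        raise SteadyStateError(
            f"steady state did not converge (max residual {max(map(abs, res)):.3e}) "
            f"for params={params} at input={inp}"
        )
    return skps[0], rrp


def integrate_to_steady_state(
    params: TCSParameters,
    inp: float,
    t_final: float = 1e6,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[float, float]:
    """Independent check: integrate the ODEs from (SK~P, RR~P) = (0, 0).

    Long-time integration (default 1e6 s, far beyond the slowest kinetic
    time scale of the default rates) from the unphosphorylated state.
    """
    if inp < 0:
        raise ValueError("input must be >= 0")
    ka = params.kappa * params.k_auto(inp)
    kp = params.phi * params.k_phos(inp)
    kt, s_tot, r_tot, k_bg = (
        params.k_transfer, params.sk_tot, params.rr_tot, params.k_dephos_bg,
    )

    def rhs(_t, y):
        skp, rrp = y
        dskp = ka * (s_tot - skp) - kt * skp * (r_tot - rrp)
        drrp = kt * skp * (r_tot - rrp) - kp * (s_tot - skp) * rrp - k_bg * rrp
        return [dskp, drrp]

    sol = solve_ivp(rhs, (0.0, t_final), [0.0, 0.0], method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SteadyStateError(f"ODE integration failed: {sol.message}")
    skp, rrp = sol.y[:, -1]
    return float(skp), float(rrp)


# ---------------------------------------------------------------------------
# transfer functions, thresholds, sweeps
# ---------------------------------------------------------------------------


def simulate_transfer_function(
    params: TCSParameters,
    promoter: PromoterModel | None = None,
    input_grid: Sequence[float] | None = None,
) -> TransferCurve:
    """Transcriptional-output transfer function over an input grid."""
    promoter = promoter or default_promoter()
    grid = np.asarray(
        default_input_grid(params) if input_grid is None else input_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("input_grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("input_grid must be strictly increasing")
    outputs = np.empty_like(grid)
    for i, inp in enumerate(grid):
        try:
            _, rrp = steady_state(params, float(inp))
        except SteadyStateError as exc:
            raise SteadyStateError(f"at input={inp}: {exc}") from exc
        outputs[i] = promoter.output(rrp)
    return TransferCurve(grid, outputs, metadata={
        "kappa": params.kappa, "phi": params.phi, "coupling": params.coupling,
    })


def k_half_of_curve(curve: TransferCurve) -> float:
    """Detection threshold K_1/2: input where output crosses (min+max)/2.

    Located by log-linear interpolation between the bracketing grid points
    (a zero-input point, if present, is never interpolated across).  If
    several intervals bracket half-max within 1e-12 jitter, the lowest-input
    bracket wins.
    """
    out = curve.outputs
    lo, hi = float(out.min()), float(out.max())
    if hi <= lo:
        raise ThresholdError("flat curve: detection threshold undefined")
    half = 0.5 * (lo + hi)
    x, y = curve.inputs, out
    for i in range(len(x) - 1):
        if x[i] <= 0:
            continue  # never interpolate across the zero-input point
        y0, y1 = y[i], y[i + 1]
        if (y0 - half) * (y1 - half) <= 1e-12 and min(y0, y1) - 1e-12 <= half <= max(y0, y1) + 1e-12:
            if y1 == y0:
                return float(x[i])
            t = (half - y0) / (y1 - y0)
            return float(10 ** (np.log10(x[i]) + t * (np.log10(x[i + 1]) - np.log10(x[i]))))
    raise ThresholdError("half-maximal output is not bracketed by the input grid")


def _curve_metrics(curve: TransferCurve) -> tuple[float, float, float, bool]:
    lo, hi = float(curve.outputs.min()), float(curve.outputs.max())
    amplitude = hi - lo
    dynamic = np.inf if lo == 0 else hi / lo
    flat = hi <= lo * (1 + 1e-12) if lo > 0 else hi == lo
    if flat:
        return np.nan, dynamic, amplitude, True
    return k_half_of_curve(curve), dynamic, amplitude, False


def sweep_activity(
    params: TCSParameters,
    promoter: PromoterModel | None = None,
    which: Literal["kinase", "phosphatase"] = "phosphatase",
    scales: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
    input_grid: Sequence[float] | None = None,
) -> SweepResult:
    """Sweep kinase (kappa) or phosphatase (phi) activity over scale factors.

    Per scale, records K_1/2, dynamic range (max/min output) and amplitude
    range (max - min).  Flat curves are flagged, not dropped.  The default
    grid spans 8 decades around k_input_half so that thresholds shifted by
    extreme scales remain bracketed.
    """
    if which not in ("kinase", "phosphatase"):
        raise ValueError("which must be 'kinase' or 'phosphatase'")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be > 0")
    promoter = promoter or default_promoter()
    if input_grid is None:
        k = params.k_input_half
        input_grid = np.concatenate(
            [[0.0], np.logspace(np.log10(k) - 4, np.log10(k) + 4, 65)]
        )
    rows = []
    for s in scales:
        p = replace(params, kappa=params.kappa * s) if which == "kinase" \
            else replace(params, phi=params.phi * s)
        curve = simulate_transfer_function(p, promoter, input_grid)
        k_half, dyn, amp, flat = _curve_metrics(curve)
        rows.append(SweepRow(float(s), k_half, dyn, amp, flat))
    return SweepResult(which, rows)


def isosk_transfer(
    params_wt: TCSParameters,
    phi_mut: float,
    fraction_wt: float,
    promoter: PromoterModel | None = None,
    input_grid: Sequence[float] | None = None,
) -> TransferCurve:
    """Transfer function of a wild-type/mutant SK mixture sharing one RR.

    Total SK is held at ``params_wt.sk_tot``, split ``fraction_wt`` to a
    wild-type pool (phi = params_wt.phi) and the rest to a mutant pool with
    phosphatase scale ``phi_mut``; both pools phosphorylate and
    dephosphorylate the single RR pool (the iso-SK design).
    """
    if not 0.0 <= fraction_wt <= 1.0:
        raise ValueError(f"fraction_wt must be in [0, 1], got {fraction_wt}")
    if phi_mut < 0:
        raise ValueError("phi_mut must be >= 0")
    promoter = promoter or default_promoter()
    grid = np.asarray(
        default_input_grid(params_wt) if input_grid is None else input_grid,
        dtype=float,
    )
    if np.any(np.diff(grid) <= 0):
        raise ValueError("input_grid must be strictly increasing")
    s_tot = params_wt.sk_tot
    outputs = np.empty_like(grid)
    for i, inp in enumerate(grid):
        inp = float(inp)
        ka = params_wt.kappa * params_wt.k_auto(inp)
        kp = params_wt.k_phos(inp)
        pools = [
            (fraction_wt * s_tot, ka, params_wt.phi * kp),
            ((1.0 - fraction_wt) * s_tot, ka, phi_mut * kp),
        ]
        skps, rrp = _solve_pools(pools, params_wt.k_transfer, params_wt.rr_tot,
                                 params_wt.k_dephos_bg)
        res = _residuals(pools, params_wt.k_transfer, params_wt.rr_tot,
                         params_wt.k_dephos_bg, skps, rrp)
        if max(abs(r) for r in res) > RESIDUAL_TOL:
            raise SteadyStateError(
                f"iso-SK steady state did not converge at input={inp} "
                f"(fraction_wt={fraction_wt}, phi_mut={phi_mut})"
            )
        outputs[i] = promoter.output(rrp)
    return TransferCurve(grid, outputs, metadata={
        "fraction_wt": fraction_wt, "phi_mut": phi_mut,
    })
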