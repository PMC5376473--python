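"""Propofol pharmacokinetics and the sigmoid Emax effect link.

Forward model
-------------
A three-compartment mammillary PK model with first-order elimination:
amounts A1 (central), A2 (rapid peripheral), A3 (slow peripheral) in
mg evolve as

    dA1/dt = u(t) - (Cl + Q1 + Q2)/V1 * A1 + Q1/V2 * A2 + Q2/V3 * A3
    dA2/dt = Q1/V1 * A1 - Q1/V2 * A2
    dA3/dt = Q2/V1 * A1 - Q2/V3 * A3

with volumes in L, clearances in L/min and infusion rate u in mg/min;
the plasma concentration is Cp = A1/V1 in mg/L = ug/mL. Plasma is
linked to a hypothetical effect site by dCe/dt = ke0 (Cp - Ce), and
an EEG index responds to Ce through the sigmoid Emax (Hill) relation

    E(Ce) = E0 + (Emax - E0) Ce^g / (Ce50^g + Ce^g).

The default PK parameter set is the published population estimate for
microemulsion propofol (V1 17.5 L at LBM 48 kg, V2 96.3 L, V3 1460 L,
Cl 1.13 L/min, Q1 1.03 L/min, Q2 0.894 L/min).

Fitting
-------
:class:`SigmoidEmaxModel` fits (E0, Emax, Ce50, gamma, ke0) to an
index time course given the plasma-concentration curve, by bounded
nonlinear least squares with multistart initialization, statsmodels
style: ``SigmoidEmaxModel(...).fit()`` returns a
:class:`SigmoidEmaxResults` carrying estimates, standard errors and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "PKParams",
    "InfusionSchedule",
    "PDModel",
    "propofol_pk_params",
    "simulate_pk",
    "effect_site",
    "sigmoid_emax",
    "SigmoidEmaxModel",
    "SigmoidEmaxResults",
    "fit_pd",
    "lrt_threshold",
]


@dataclass(frozen=True)
class PKParams:
    """Three-compartment model constants (volumes L, clearances L/min)."""

    V1: float
    V2: float
    V3: float
    Cl: float
    Q1: float
    Q2: float

    def __post_init__(self) -> None:
        for name in ("V1", "V2", "V3", "Q1", "Q2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.Cl < 0:
            raise ValueError("Cl must be non-negative")

    def rate_matrix(self) -> np.ndarray:
        return np.array(
            [
                [-(self.Cl + self.Q1 + self.Q2) / self.V1, self.Q1 / self.V2, self.Q2 / self.V3],
                [self.Q1 / self.V1, -self.Q1 / self.V2, 0.0],
                [self.Q2 / self.V1, 0.0, -self.Q2 / self.V3],
            ]
        )


def propofol_pk_params(lbm_kg: float | None = None) -> PKParams:
    """Published population PK estimates; V1 scales linearly with LBM/48."""
    v1 = 17.5 if lbm_kg is None else 17.5 * (lbm_kg / 48.0)
    return PKParams(V1=v1, V2=96.3, V3=1460.0, Cl=1.13, Q1=1.03, Q2=0.894)


@dataclass
class InfusionSchedule:
    """Piecewise-constant infusion: (start_min, rate_mg_per_min, duration_min)."""

    segments: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        segs = sorted((float(a), float(r), float(d)) for a, r, d in self.segments)
        for start, rate, dur in segs:
            if rate < 0:
                raise ValueError("infusion rates must be non-negative")
            if dur <= 0:
                raise ValueError("segment durations must be positive")
        for (s0, _, d0), (s1, _, _) in zip(segs, segs[1:]):
            if s0 + d0 > s1:
                raise ValueError("infusion segments must not overlap")
        self.segments = segs

    @property
    def end_min(self) -> float:
        return max((s + d for s, _, d in self.segments), default=0.0)

    def rate_at(self, t_min: float) -> float:
        for start, rate, dur in self.segments:
            if start <= t_min < start + dur:
                return rate
        return 0.0

    def breakpoints(self) -> list[float]:
        pts: set[float] = set()
        for start, _, dur in self.segments:
            pts.update((start, start + dur))
        return sorted(pts)


def _propagate(M: np.ndarray, A: np.ndarray, rate: float, dt: float) -> np.ndarray:
    """Exact step of dA/dt = M A + [rate,0,0] over dt via augmented expm."""
    aug = np.zeros((4, 4))
    aug[:3, :3] = M * dt
    aug[0, 3] = rate * dt
    ph = linalg.expm(aug)
    return ph[:3, :3] @ A + ph[:3, 3]


def simulate_pk(
    params: PKParams,
    schedule: InfusionSchedule,
    t_grid_min: np.ndarray,
    return_amounts: bool = False,
) -> np.ndarray:
    """Central-compartment concentration Cp (ug/mL) on ``t_grid_min``.

    The system is linear with piecewise-constant input, so propagation
    uses the matrix exponential segment by segment — exact up to
    floating point, no integrator tolerance involved. With
    ``return_amounts`` the full (n, 3) compartment amounts in mg are
    returned instead (mass balance checks).
    """
    t_grid = np.asarray(t_grid_min, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid_min must be strictly increasing")
    M = params.rate_matrix()
    events = [b for b in schedule.breakpoints() if b > 0]
    amounts = np.empty((len(t_grid), 3))
    A = np.zeros(3)
    t_cur = 0.0
    for i, t in enumerate(t_grid):
        if t < 0:
            raise ValueError("t_grid_min must be non-negative")
        while events and events[0] <= t:
            b = events.pop(0)
            if b > t_cur:
                A = _propagate(M, A, schedule.rate_at(t_cur), b - t_cur)
                t_cur = b
        if t > t_cur:
            A = _propagate(M, A, schedule.rate_at(t_cur), t - t_cur)
            t_cur = t
        amounts[i] = A
    if return_amounts:
        return amounts
    return amounts[:, 0] / params.V1


def effect_site(t_min: np.ndarray, cp: np.ndarray, ke0: float) -> np.ndarray:
    """Effect-site concentration from dCe/dt = ke0 (Cp - Ce), Ce(0)=0.

    ``cp`` is treated as piecewise linear between grid points, for
    which the first-order ODE has a closed-form update per interval.
    """
    if ke0 <= 0:
        raise ValueError("ke0 must be strictly positive")
    t = np.asarray(t_min, dtype=float)
    cp = np.asarray(cp, dtype=float)
    ce = np.zeros_like(cp)
    dt = np.diff(t)
    decay = np.exp(-ke0 * dt)
    slope = np.diff(cp) / dt
    for i in range(len(dt)):
        a, b, e = cp[i], slope[i], decay[i]
        ce[i + 1] = a + b * dt[i] - b / ke0 + (ce[i] - a + b / ke0) * e
    return ce


@dataclass(frozen=True)
class PDModel:
    """Sigmoid Emax parameters linking Ce (ug/mL) to an index value."""

    E0: float
    Emax: float
    Ce50: float
    gamma: float
    ke0: float

    def __post_init__(self) -> None:
        if self.Ce50 <= 0 or self.gamma <= 0 or self.ke0 <= 0:
            raise ValueError("Ce50, gamma and ke0 must be strictly positive")


def sigmoid_emax(pd: PDModel, ce: np.ndarray | float) -> np.ndarray | float:
    """E(Ce) = E0 + (Emax - E0) Ce^g / (Ce50^g + Ce^g)."""
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValueError("Ce must be non-negative")
    frac = np.zeros_like(ce_arr)
    pos = ce_arr > 0
    ratio = (ce_arr[pos] / pd.Ce50) ** pd.gamma
    frac[pos] = ratio / (1.0 + ratio)
    out = pd.E0 + (pd.Emax - pd.E0) * frac
    return float(out) if np.isscalar(ce) else out


class SigmoidEmaxModel:
    """Effect-compartment sigmoid Emax model for one index course.

    Parameters
    ----------
    times_min, values : array
        The observed index course (window times in minutes).
    cp_times_min, cp : array
        The plasma-concentration curve, on its own (finer) grid; Ce is
        recomputed from it for every candidate ke0 during fitting.
    """

    param_names = ("E0", "Emax", "Ce50", "gamma", "ke0")

    def __init__(self, times_min, values, cp_times_min, cp):
        self.times_min = np.asarray(times_min, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.cp_times_min = np.asarray(cp_times_min, dtype=float)
        self.cp = np.asarray(cp, dtype=float)
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.cp_times_min.shape != self.cp.shape:
            raise ValueError("cp grid and values must have equal length")
        if len(self.times_min) < 6:
            raise ValueError("need at least 6 points to fit 5 parameters")

    def predict(self, pd: PDModel, times_min: np.ndarray | None = None) -> np.ndarray:
        ce = effect_site(self.cp_times_min, self.cp, pd.ke0)
        t = self.times_min if times_min is None else np.asarray(times_min, float)
        return sigmoid_emax(pd, np.interp(t, self.cp_times_min, ce))

    # internal parameterization: (E0, Emax, ln Ce50, ln gamma, ln ke0)
    def _residual(self, theta: np.ndarray) -> np.ndarray:
        pd = PDModel(theta[0], theta[1], np.exp(theta[2]), np.exp(theta[3]), np.exp(theta[4]))
        return self.predict(pd) - self.values

    def _starts(self) -> list[np.ndarray]:
        e0 = float(np.mean(self.values[: max(3, len(self.values) // 10)]))
        emax = float(self.values[np.argmax(self.cp_interp())])
        ce_scale = max(float(np.max(self.cp)), 1e-3)
        starts = []
        for ke0 in (0.05, 0.15, 0.5):
            for gamma in (1.5, 4.0):
                for ce50 in (0.3 * ce_scale, 0.6 * ce_scale):
                    starts.append(
                        np.array([e0, emax, np.log(ce50), np.log(gamma), np.log(ke0)])
                    )
        return starts

    def cp_interp(self) -> np.ndarray:
        return np.interp(self.times_min, self.cp_times_min, self.cp)

    def fit(self, n_best: int = 1, xtol: float = 1e-12) -> "SigmoidEmaxResults":
        """Multistart bounded least squares; returns the best solution."""
        best = None
        n_ok = 0
        for theta0 in self._starts():
            try:
                sol = optimize.least_squares(
                    self._residual, theta0, method="trf", xtol=xtol, ftol=1e-12
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or n_ok == 0:
            raise RuntimeError("sigmoid Emax fit failed from every start")
        theta = best.x
        pd = PDModel(theta[0], theta[1], np.exp(theta[2]), np.exp(theta[3]), np.exp(theta[4]))
        sse = float(2.0 * best.cost)
        return SigmoidEmaxResults(self, pd, sse, best)


@dataclass
class SigmoidEmaxResults:
    """Fitted sigmoid Emax model: estimates, uncertainty, diagnostics."""

    model: SigmoidEmaxModel
    pd: PDModel
    sse: float
    _solution: object = field(repr=False, default=None)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.pd.E0, self.pd.Emax, self.pd.Ce50, self.pd.gamma, self.pd.ke0])

    @property
    def nobs(self) -> int:
        return len(self.model.values)

    @property
    def df_resid(self) -> int:
        return self.nobs - 5

    @property
    def scale(self) -> float:
        return self.sse / max(self.df_resid, 1)

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors from the Gauss-Newton Hessian.

        Computed on the internal (log for positive parameters) scale
        and mapped back by the delta method; NaN where the Hessian is
        singular (e.g. a degenerate flat-course fit).
        """
        J = self._solution.jac
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cov_theta = self.scale * np.linalg.inv(J.T @ J)
            except np.linalg.LinAlgError:
                return np.full(5, np.nan)
        se_theta = np.sqrt(np.clip(np.diag(cov_theta), 0, np.inf))
        jac_back = np.array([1.0, 1.0, self.pd.Ce50, self.pd.gamma, self.pd.ke0])
        return se_theta * jac_back

    @property
    def degenerate(self) -> bool:
        """True when the fitted effect span is negligible (Emax ~= E0)."""
        span = abs(self.pd.Emax - self.pd.E0)
        scale = max(abs(self.pd.E0), float(np.std(self.model.values)), 1e-12)
        return span < 1e-3 * scale

    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.pd)

    def summary(self) -> str:
        lines = [
            "Sigmoid Emax effect-compartment fit",
            "=" * 47,
            f"{'n obs':<12}{self.nobs:>10}    {'SSE':<8}{self.sse:>12.6g}",
            f"{'df resid':<12}{self.df_resid:>10}    {'scale':<8}{self.scale:>12.6g}",
            "-" * 47,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(self.model.param_names, self.params, self.bse):
            lines.append(f"{name:<8}{est:>12.5g}{se:>12.3g}")
        if self.degenerate:
            lines.append("WARNING: degenerate fit (Emax ~= E0); course carries no drug effect")
        lines.append("=" * 47)
        return "\n".join(lines)


def fit_pd(
    times_min, values, cp_times_min, cp
) -> SigmoidEmaxResults:
    """Convenience wrapper: build :class:`SigmoidEmaxModel` and fit."""
    return SigmoidEmaxModel(times_min, values, cp_times_min, cp).fit()


def lrt_threshold(alpha: float = 0.05, df: int = 1) -> float:
    """Objective-function drop needed at level ``alpha`` (chi-square LRT)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be a positive integer")
    return float(stats.chi2.ppf(1.0 - alpha, df))
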