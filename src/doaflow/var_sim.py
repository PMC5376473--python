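"""VAR(1) simulation with analytic oracles, and the anesthesia fixture.

The generator is a first-order vector autoregression

    x_t = F x_{t-1} + e_t,    e_t ~ N(0, Q)

with ``F[i, j]`` the coupling strength from source channel j into
target channel i. Stationarity requires the spectral radius of F to
be below 1, in which case the lag-0 covariance solves the discrete
Lyapunov equation S = F S F' + Q and the lag-tau cross-covariance is
F^tau S. Plugging these population covariances into the Gaussian TE
expression gives an exact oracle against which the sample estimator
can be checked.

The anesthesia fixture emulates a 7-channel frontoparietal recording
whose inter-channel couplings are attenuated by the simulated
effect-site concentration of propofol: a designated set of F entries
is scaled by g(Ce) = 1 / (1 + (Ce / C50)^h), so rising Ce weakens
directed connectivity (the loss-of-consciousness signature) while
falling Ce restores it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .io import EEGRecording
from .infotheory import te_from_lagged_cov
from .pkpd import InfusionSchedule, PKParams, effect_site, propofol_pk_params, simulate_pk

__all__ = [
    "VARModel",
    "simulate_var",
    "stationary_covariance",
    "lagged_stationary_cov",
    "analytic_te",
    "random_stable_var",
    "AnesthesiaFixtureSpec",
    "make_anesthesia_fixture",
    "STANDARD_CHANNELS",
]

STANDARD_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "P3", "P4", "Cz")


@dataclass
class VARModel:
    """Stationary VAR(1): coupling matrix, innovation covariance, labels."""

    F: np.ndarray
    noise_cov: np.ndarray | None = None
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        n = self.F.shape[0]
        if self.F.shape != (n, n):
            raise ValueError("F must be square")
        if self.noise_cov is None:
            self.noise_cov = np.eye(n)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.noise_cov.shape != (n, n):
            raise ValueError("noise_cov must match F")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.noise_cov) <= 0):
            raise ValueError("noise_cov must be positive definite")
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(n))
        if len(self.labels) != n:
            raise ValueError("labels must match dimension")

    @property
    def n_channels(self) -> int:
        return self.F.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.F))))

    def check_stable(self) -> None:
        rho = self.spectral_radius
        if rho >= 1:
            raise ValueError(f"unstable VAR: spectral radius {rho:.4f} >= 1")


def simulate_var(
    model: VARModel,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    fs: float = 256.0,
    burn_in: int = 1000,
) -> EEGRecording:
    """Draw a stationary realization as an :class:`EEGRecording`.

    The first ``burn_in`` samples are discarded so the output starts
    at (approximate) stationarity; a fixed seed fixes the realization.
    """
    model.check_stable()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = model.n_channels
    chol = np.linalg.cholesky(model.noise_cov)
    noise = rng.standard_normal((burn_in + n_samples, n)) @ chol.T
    out = np.empty((burn_in + n_samples, n))
    x = np.zeros(n)
    for t in range(burn_in + n_samples):
        x = model.F @ x + noise[t]
        out[t] = x
    return EEGRecording(list(model.labels), fs, out[burn_in:])


def stationary_covariance(model: VARModel, tau: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Lag-0 covariance and lag-``tau`` cross-covariance cov(x_{t+tau}, x_t)."""
    model.check_stable()
    sigma0 = linalg.solve_discrete_lyapunov(model.F, model.noise_cov)
    sigma0 = (sigma0 + sigma0.T) / 2
    return sigma0, np.linalg.matrix_power(model.F, tau) @ sigma0


def lagged_stationary_cov(model: VARModel, tau: int = 1) -> np.ndarray:
    """Population analogue of :func:`doaflow.infotheory.lagged_covariance`."""
    sigma0, cross = stationary_covariance(model, tau)
    return np.block([[sigma0, cross], [cross.T, sigma0]])


def analytic_te(
    model: VARModel,
    target: tuple[str, ...] | list[str],
    source: tuple[str, ...] | list[str],
    tau: int = 1,
) -> float:
    """Exact Gaussian TE from population covariances of the VAR."""
    if set(target) & set(source):
        raise ValueError("target and source must be disjoint")
    pos = {lab: i for i, lab in enumerate(model.labels)}
    names = list(target) + list(source)
    missing = [c for c in names if c not in pos]
    if missing:
        raise KeyError(f"channels not in model: {missing}")
    cov2n = lagged_stationary_cov(model, tau)
    idx = [pos[c] for c in names]
    sel = np.concatenate([idx, [p + model.n_channels for p in idx]])
    sub = cov2n[np.ix_(sel, sel)]
    k = len(names)
    return te_from_lagged_cov(
        sub, k, list(range(len(target))), list(range(len(target), k))
    )


def random_stable_var(
    n: int, seed: int | np.random.Generator = 0, coupling: float = 0.9
) -> VARModel:
    """A random VAR(1) rescaled to spectral radius ``coupling`` < 1."""
    if not 0 < coupling < 1:
        raise ValueError("coupling must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    F = rng.standard_normal((n, n))
    F *= coupling / np.max(np.abs(np.linalg.eigvals(F)))
    return VARModel(F)


def _base_anesthesia_F() -> np.ndarray:
    """Frontoparietal coupling pattern for the 7 standard channels.

    Row = target, column = source. Feedback (frontal -> parietal)
    couplings are the strongest, feedforward return paths weaker,
    matching the qualitative asymmetry seen during wakefulness.
    """
    c = {name: i for i, name in enumerate(STANDARD_CHANNELS)}
    F = np.eye(7) * 0.5
    # bidirectional network: every channel receives input across any
    # cut, so even the weakest bipartition carries non-trivial flow
    edges = {
        ("Fp1", "Fp2"): 0.15, ("Fp2", "Fp1"): 0.15,
        ("Fp1", "F3"): 0.10, ("Fp2", "F4"): 0.10,
        ("F3", "Fp1"): 0.20, ("F4", "Fp2"): 0.20,
        ("P3", "F3"): 0.30, ("P4", "F4"): 0.30,      # feedback pathways
        ("P3", "Fp1"): 0.15, ("P4", "Fp2"): 0.15,
        ("F3", "P3"): 0.10, ("F4", "P4"): 0.10,       # feedforward return
        ("F3", "Cz"): 0.10, ("F4", "Cz"): 0.10,
        ("P3", "Cz"): 0.10, ("P4", "Cz"): 0.10,
        ("Cz", "F3"): 0.10, ("Cz", "F4"): 0.10,
        ("Cz", "P3"): 0.10, ("Cz", "P4"): 0.10,
    }
    for (tgt, src), w in edges.items():
        F[c[tgt], c[src]] = w
    return F


@dataclass
class AnesthesiaFixtureSpec:
    """Everything needed to synthesize one anesthesia recording.

    The infusion schedule drives a 3-compartment PK model; the plasma
    concentration feeds a first-order effect compartment (rate ke0);
    the resulting Ce(t) attenuates the designated couplings by
    g(Ce) = 1/(1 + (Ce/c50_mod)^h_mod). ``modulated`` lists (target,
    source) label pairs; None modulates every off-diagonal coupling
    (anesthetic suppression of inter-regional connectivity at large).
    """

    fs: float = 256.0
    duration_s: float = 1200.0
    base_F: np.ndarray | None = None
    noise_cov: np.ndarray | None = None
    labels: tuple[str, ...] = STANDARD_CHANNELS
    schedule: InfusionSchedule | None = None
    pk_params: PKParams | None = None
    ke0_per_min: float = 0.25
    c50_mod: float = 1.2     # ug/mL at which couplings are halved
    h_mod: float = 2.5
    modulated: list[tuple[str, str]] | None = None
    seed: int = 0


@dataclass
class AnesthesiaGroundTruth:
    """Per-sample latent state underlying a synthetic recording."""

    times_s: np.ndarray
    ce: np.ndarray           # effect-site concentration, ug/mL
    g: np.ndarray            # coupling attenuation factor in (0, 1]
    base_F: np.ndarray
    modulated_mask: np.ndarray
    infusion_start_s: float
    infusion_end_s: float

    def F_at(self, i: int) -> np.ndarray:
        F = self.base_F.copy()
        F[self.modulated_mask] *= self.g[i]
        return F


def make_anesthesia_fixture(
    spec: AnesthesiaFixtureSpec,
) -> tuple[EEGRecording, AnesthesiaGroundTruth]:
    """Synthesize an anesthesia-modulated 7-channel recording.

    Returns the recording (with infusion annotations) and per-sample
    ground truth (Ce, attenuation g, coupling matrices) for
    parameter-recovery tests.
    """
    base_F = _base_anesthesia_F() if spec.base_F is None else np.asarray(spec.base_F, float)
    n = base_F.shape[0]
    labels = tuple(spec.labels)[:n]
    base = VARModel(base_F, spec.noise_cov, labels)
    base.check_stable()

    schedule = spec.schedule
    if schedule is None:
        # 12 mg/kg/h at a nominal 70 kg for the middle half of the record
        t0, dur = spec.duration_s / 4 / 60.0, spec.duration_s / 2 / 60.0
        schedule = InfusionSchedule([(t0, 14.0, dur)])
    pk = spec.pk_params if spec.pk_params is not None else propofol_pk_params()

    n_samples = round(spec.duration_s * spec.fs)
    t_s = np.arange(n_samples) / spec.fs
    t_min_grid = np.arange(0.0, spec.duration_s / 60.0 + 1 / 60.0, 1 / 60.0)
    cp = simulate_pk(pk, schedule, t_min_grid)
    ce_grid = effect_site(t_min_grid, cp, spec.ke0_per_min)
    ce = np.interp(t_s / 60.0, t_min_grid, ce_grid)
    g = 1.0 / (1.0 + (ce / spec.c50_mod) ** spec.h_mod)

    if spec.modulated is None:
        mask = (base_F != 0) & ~np.eye(n, dtype=bool)
    else:
        pos = {lab: i for i, lab in enumerate(labels)}
        mask = np.zeros((n, n), dtype=bool)
        for tgt, src in spec.modulated:
            mask[pos[tgt], pos[src]] = True

    # attenuation only shrinks couplings, so stability of the base
    # model (non-negative F) carries over; verify at strongest level
    F_deep = base_F.copy()
    F_deep[mask] *= g.min()
    VARModel(F_deep, spec.noise_cov, labels).check_stable()

    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(base.noise_cov)
    burn = 1000
    noise = rng.standard_normal((burn + n_samples, n)) @ chol.T
    out = np.empty((burn + n_samples, n))
    x = np.zeros(n)
    Fmod = base_F[mask]
    F = base_F.copy()
    for t in range(burn + n_samples):
        gi = g[0] if t < burn else g[t - burn]
        F[mask] = Fmod * gi
        x = F @ x + noise[t]
        out[t] = x

    start_s = schedule.segments[0][0] * 60.0
    end_s = schedule.end_min * 60.0
    rec = EEGRecording(
        list(labels),
        spec.fs,
        out[burn:],
        annotations=[
            (min(start_s, spec.duration_s), "infusion_start"),
            (min(end_s, spec.duration_s), "infusion_end"),
        ],
    )
    truth = AnesthesiaGroundTruth(
        times_s=t_s,
        ce=ce,
        g=g,
        base_F=base_F,
        modulated_mask=mask,
        infusion_start_s=start_s,
        infusion_end_s=end_s,
    )
    return rec, truth
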