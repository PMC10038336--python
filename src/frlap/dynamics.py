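"""Excited-state population dynamics on the Förster rate network.

The single-excitation master equation dp/dt = K p is propagated through an
eigendecomposition of the generator augmented with explicit decay and trap
sink states, so that the cumulative decayed/trapped fractions are available
and total probability is conserved to numerical precision.  Trapping
efficiency and mean first-passage times are computed analytically through
linear solves on the (sub-)generator; a vectorised Gillespie kinetic
Monte Carlo sampler serves as an independent stochastic cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .photophysics import RateMatrix

__all__ = [
    "PopulationTrajectories",
    "MultiExpFit",
    "propagate",
    "fit_multiexponential",
    "trapping_efficiency",
    "mean_first_passage_time",
    "kinetic_monte_carlo",
    "default_time_grid",
]


def default_time_grid(t_min_ps: float = 1e-3, t_max_ps: float = 1e4,
                      n: int = 400) -> np.ndarray:
    """Log-spaced time grid, 1 fs to 10 ns by default."""
    return np.geomspace(t_min_ps, t_max_ps, n)


@dataclass
class PopulationTrajectories:
    time_ps: np.ndarray
    populations: np.ndarray  # (n_times, n_sites)
    decayed: np.ndarray  # cumulative fraction lost to decay
    trapped: np.ndarray  # cumulative fraction lost to the trap
    classes: np.ndarray | None = None

    def class_trace(self, subunit_class: str) -> np.ndarray:
        if self.classes is None:
            raise ValueError("no class labels attached")
        return self.populations[:, self.classes == subunit_class].sum(axis=1)

    @property
    def total(self) -> np.ndarray:
        return self.populations.sum(axis=1) + self.decayed + self.trapped


def _augmented_generator(rm: RateMatrix) -> np.ndarray:
    """Generator over [sites..., decay sink, trap sink]; columns sum to 0."""
    n = rm.n_sites
    G = np.zeros((n + 2, n + 2))
    G[:n, :n] = rm.K
    G[n, :n] = rm.decay
    G[n + 1, :n] = rm.trap
    return G


def propagate(rm: RateMatrix, p0: np.ndarray,
              time_ps: np.ndarray | None = None) -> PopulationTrajectories:
    """Solve dp/dt = K p by eigendecomposition of the augmented generator.

    Falls back to scaled matrix-exponential stepping when the eigenvector
    matrix is too ill-conditioned (defective K).
    """
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < 0):
        raise ValueError("initial populations must be non-negative")
    if not np.all(np.isfinite(rm.K)):
        raise ValueError("rate matrix contains non-finite entries")
    if time_ps is None:
        time_ps = default_time_grid()
    G = _augmented_generator(rm)
    n = rm.n_sites
    q0 = np.concatenate([p0, [0.0, 0.0]])
    w, V = np.linalg.eig(G)
    cond = np.linalg.cond(V)
    if cond < 1e10:
        c = np.linalg.solve(V, q0)
        q = np.real((np.exp(np.outer(time_ps, w)) * c[None, :]) @ V.T)
    else:  # defective generator: scaled expm stepping
        q = np.empty((len(time_ps), n + 2))
        prev_t, prev_q = 0.0, q0
        for i, t in enumerate(time_ps):
            prev_q = expm(G * (t - prev_t)) @ prev_q
            prev_t = t
            q[i] = prev_q
    return PopulationTrajectories(
        time_ps=np.asarray(time_ps, float), populations=q[:, :n],
        decayed=q[:, n], trapped=q[:, n + 1],
        classes=None)


def propagate_lattice(rm: RateMatrix, lattice, p0: np.ndarray,
                      time_ps: np.ndarray | None = None
                      ) -> PopulationTrajectories:
    """``propagate`` with per-class traces attached from a lattice."""
    traj = propagate(rm, p0, time_ps)
    traj.classes = lattice.classes
    return traj


@dataclass
class MultiExpFit:
    lifetimes_ps: np.ndarray
    amplitudes: np.ndarray
    fixed: np.ndarray  # bool per component
    residual_rms: float
    converged: bool = True
    message: str = ""

    def model(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-np.outer(t, 1.0 / self.lifetimes_ps)) @ self.amplitudes


def fit_multiexponential(time_ps: np.ndarray, trace: np.ndarray,
                         n_components: int,
                         fixed_lifetimes: dict[int, float] | None = None,
                         initial_lifetimes: np.ndarray | None = None,
                         max_nfev: int = 2000) -> MultiExpFit:
    """Sum-of-exponentials fit with variable projection.

    Free lifetimes are optimised in log space by trust-region least
    squares; at every step the amplitudes are solved linearly.
    ``fixed_lifetimes`` maps component index (in ascending-lifetime order
    of the initial guess) to a lifetime held exactly.
    """
    time_ps = np.asarray(time_ps, float)
    trace = np.asarray(trace, float)
    if len(time_ps) < 3 * n_components:
        raise ValueError("need at least 3 points per component")
    fixed_lifetimes = fixed_lifetimes or {}
    if initial_lifetimes is None:
        initial_lifetimes = np.geomspace(
            max(time_ps[time_ps > 0].min(), 1e-6), time_ps.max() / 3.0,
            n_components)
    taus = np.array(initial_lifetimes, dtype=float)
    for idx, tau in fixed_lifetimes.items():
        taus[idx] = tau
    free_idx = np.array([i for i in range(n_components)
                         if i not in fixed_lifetimes], dtype=int)

    def design(all_taus: np.ndarray) -> np.ndarray:
        return np.exp(-np.outer(time_ps, 1.0 / all_taus))

    def assemble(log_free: np.ndarray) -> np.ndarray:
        full = taus.copy()
        full[free_idx] = np.exp(log_free)
        return full

    def residual(log_free: np.ndarray) -> np.ndarray:
        D = design(assemble(log_free))
        amps, *_ = np.linalg.lstsq(D, trace, rcond=None)
        return D @ amps - trace

    if len(free_idx):
        sol = least_squares(residual, np.log(taus[free_idx]),
                            method="trf", xtol=1e-12, ftol=1e-12,
                            max_nfev=max_nfev)
        taus = assemble(sol.x)
        converged, message = sol.status > 0, sol.message
    else:
        converged, message = True, "all lifetimes fixed"
    D = design(taus)
    amps, *_ = np.linalg.lstsq(D, trace, rcond=None)
    resid = D @ amps - trace
    order = np.argsort(taus)
    return MultiExpFit(
        lifetimes_ps=taus[order], amplitudes=amps[order],
        fixed=np.isin(order, list(fixed_lifetimes)),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        converged=bool(converged), message=str(message))


def trapping_efficiency(rm: RateMatrix, p0: np.ndarray) -> float:
    """Analytic trap yield η = Σ_traps k_trap,i · [(−K)⁻¹ p0]_i ∈ [0, 1].

    ``(−K)⁻¹ p0`` is the vector of expected residence times; the trap flux
    integral over all time is then a single linear solve.
    """
    if not (rm.trap.sum() > 0):
        raise ValueError("rate matrix has no trap channel")
    if rm.decay.sum() + rm.trap.sum() <= 0:
        raise ValueError("no sink channels: infinite residence")
    residence = np.linalg.solve(-rm.K, np.asarray(p0, float))
    return float(rm.trap @ residence)


def decayed_fraction(rm: RateMatrix, p0: np.ndarray) -> float:
    residence = np.linalg.solve(-rm.K, np.asarray(p0, float))
    return float(rm.decay @ residence)


def mean_first_passage_time(rm: RateMatrix, source: int,
                            targets: np.ndarray | list[int]) -> float:
    """MFPT (ps) from ``source`` to first arrival in ``targets``.

    Decay/trap channels should normally be removed first
    (``rm.transfer_only()``).  Computed as the summed expected residence
    time in the transient states of the absorbing-target generator.
    Returns ``inf`` if the target set is unreachable.
    """
    targets = np.atleast_1d(np.asarray(targets, dtype=int))
    if targets.size == 0:
        raise ValueError("target set must be nonempty")
    if source in targets:
        return 0.0
    n = rm.n_sites
    transient = np.setdiff1d(np.arange(n), targets)
    kqq = rm.K[np.ix_(transient, transient)]
    e_s = np.zeros(len(transient))
    e_s[np.nonzero(transient == source)[0][0]] = 1.0
    try:
        residence = np.linalg.solve(-kqq, e_s)
    except np.linalg.LinAlgError:
        return float("inf")
    if np.any(residence < -1e-9) or not np.all(np.isfinite(residence)):
        return float("inf")
    return float(residence.sum())


@dataclass
class KMCResult:
    efficiency: float
    std_error: float
    exit_counts: dict[str, int]
    n_trajectories: int


def kinetic_monte_carlo(rm: RateMatrix, p0: np.ndarray, n_traj: int,
                        seed: int) -> KMCResult:
    """Gillespie sampling of single-excitation hopping, vectorised over
    trajectories.  Counts exits through the trap vs the decay channel."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    n = rm.n_sites
    K_off = rm.K.copy()
    np.fill_diagonal(K_off, 0.0)
    # per-state total exit rate and cumulative destination table
    # destinations: n sites, then decay sink (n) and trap sink (n+1)
    rates = np.concatenate([K_off, rm.decay[None, :], rm.trap[None, :]],
                           axis=0)  # (n+2, n) column j = rates out of j
    total = rates.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("every state needs at least one exit channel")
    cum = np.cumsum(rates / total[None, :], axis=0)
    state = rng.choice(n, size=n_traj, p=np.asarray(p0, float))
    active = np.ones(n_traj, dtype=bool)
    exit_channel = np.full(n_traj, -1)
    while active.any():
        idx = np.nonzero(active)[0]
        u = rng.random(len(idx))
        # destination via inverse-CDF lookup, vectorised over trajectories
        dest = (u[None, :] > cum[:, state[idx]]).sum(axis=0)
        absorbed = dest >= n
        exit_channel[idx[absorbed]] = dest[absorbed] - n
        active[idx[absorbed]] = False
        state[idx[~absorbed]] = dest[~absorbed]
    n_trap = int((exit_channel == 1).sum())
    n_decay = int((exit_channel == 0).sum())
    eff = n_trap / n_traj
    se = float(np.sqrt(max(eff * (1 - eff), 1e-12) / n_traj))
    return KMCResult(efficiency=eff, std_error=se,
                     exit_counts={"decay": n_decay, "trap": n_trap},
                     n_trajectories=n_traj)
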