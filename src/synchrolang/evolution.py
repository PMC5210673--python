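"""Replace-worst evolutionary dynamics over reception-noise levels.

Each evolutionary step scores every agent by its mean h_i over one or more
synchronization events, then replaces the noise level of the worst-scoring
agent with a noisy copy of the best-scoring agent's level: the new value is
drawn from U((1-theta)*eps_top, (1+theta)*eps_top) and clamped to [0, 180],
where theta is the copying error.  Network positions are fixed; only the
noise value is inherited.

Depending on the cost ratio beta/alpha the population either collapses to
maximal noise (free-riding wins: precision is too expensive) or slowly
evolves towards low noise (efficient communication wins).  The module also
provides the phase-diagram sweep over (alpha, beta) and a deterministic
best-response iteration in which a common group noise level repeatedly moves
to the focal agent's best response — the gradual route to fluency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import sample_event
from .network import SocialNetwork
from .payoffs import best_response_noise, event_payoffs

__all__ = [
    "EvolutionParams",
    "EvolutionStep",
    "EvolutionTrajectory",
    "evolution_step",
    "score_population",
    "run_evolution",
    "phase_diagram",
    "best_response_dynamics",
]


@dataclass(frozen=True)
class EvolutionParams:
    """Configuration of one evolutionary run.

    ``payoff_reps`` is the number of synchronization events averaged when
    scoring agents each step (1 = score on a single event).  A fresh graph
    and fresh initial headings are drawn per event unless ``network`` fixes
    the graph.
    """

    n: int = 10
    k: int = 4
    tau: int = 40
    alpha: float = 1.0
    beta: float = 0.1
    theta: float = 0.05
    eps0: float = 10.0
    steps: int = 2000
    payoff_reps: int = 1
    network: SocialNetwork | None = None

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        if not 0.0 <= self.eps0 <= 180.0:
            raise ValueError(f"eps0 must lie in [0, 180], got {self.eps0}")
        if self.steps < 0:
            raise ValueError(f"steps must be >= 0, got {self.steps}")
        if self.payoff_reps < 1:
            raise ValueError(f"payoff_reps must be >= 1, got {self.payoff_reps}")


@dataclass(frozen=True)
class EvolutionStep:
    eps: np.ndarray
    replaced: int
    copied_from: int


def evolution_step(
    eps: np.ndarray,
    scores: np.ndarray,
    theta: float,
    rng: np.random.Generator,
) -> EvolutionStep:
    """One replace-worst step on the noise vector.

    The lowest-scoring agent's eps is replaced by a draw from
    U((1-theta)*eps_top, (1+theta)*eps_top) around the highest-scoring
    agent's value, clamped into [0, 180].  Score ties go to the lowest agent
    id for both roles; if the same agent is worst and best it self-copies
    with mutation.  Exactly one entry changes.
    """
    eps = np.asarray(eps, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if eps.size == 0:
        raise ValueError("population is empty")
    if eps.size != scores.size:
        raise ValueError(f"size mismatch: {eps.size} noise levels, {scores.size} scores")
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    drop = int(np.argmin(scores))
    top = int(np.argmax(scores))
    eps_top = eps[top]
    lo, hi = (1.0 - theta) * eps_top, (1.0 + theta) * eps_top
    new_val = float(np.clip(rng.uniform(lo, hi), 0.0, 180.0))
    out = eps.copy()
    out[drop] = new_val
    return EvolutionStep(eps=out, replaced=drop, copied_from=top)


def score_population(
    eps: np.ndarray,
    params: EvolutionParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-agent mean h_i over ``payoff_reps`` independent events."""
    eps = np.asarray(eps, dtype=float)
    h_sum = np.zeros(params.n)
    for _ in range(params.payoff_reps):
        res = sample_event(params.n, params.k, params.tau, eps, rng, network=params.network)
        h_sum += event_payoffs(res, eps, params.alpha, params.beta)
    return h_sum / params.payoff_reps


@dataclass(frozen=True)
class EvolutionTrajectory:
    params: EvolutionParams
    eps_history: np.ndarray  # (steps+1, n)
    payoff_history: np.ndarray  # (steps, n)
    replaced: np.ndarray  # (steps,)
    copied_from: np.ndarray  # (steps,)

    @property
    def mean_eps_history(self) -> np.ndarray:
        return self.eps_history.mean(axis=1)

    @property
    def final_mean_eps(self) -> float:
        return float(self.eps_history[-1].mean())

    def first_step_reaching(self, level: float, above: bool) -> int | None:
        """First evolutionary step at which mean eps crosses ``level``.

        ``above=True`` looks for mean eps > level, else mean eps < level;
        returns None if the trajectory never reaches it.
        """
        m = self.mean_eps_history
        hits = np.nonzero(m > level if above else m < level)[0]
        return int(hits[0]) if hits.size else None

    def converged(self, window_frac: float = 0.1, tol: float = 1.0) -> bool:
        """Rolling-stability diagnostic: mean eps varies < ``tol`` degrees
        over the trailing ``window_frac`` of steps."""
        m = self.mean_eps_history
        w = max(2, int(len(m) * window_frac))
        tail = m[-w:]
        return bool(tail.max() - tail.min() < tol)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-agent trajectory (step, agent_id, eps, h_i, ...)."""
        s_max, n = self.eps_history.shape
        rows = []
        for s in range(s_max):
            for a in range(n):
                rows.append(
                    (
                        s,
                        a,
                        self.eps_history[s, a],
                        self.payoff_history[s - 1, a] if s > 0 else np.nan,
                        s > 0 and a == self.replaced[s - 1],
                        self.copied_from[s - 1] if s > 0 and a == self.replaced[s - 1] else -1,
                    )
                )
        return pd.DataFrame(
            rows, columns=["step", "agent_id", "eps", "h_i", "replaced_flag", "copied_from"]
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(self.eps_history.shape[0]),
                "mean_eps": self.eps_history.mean(axis=1),
                "min_eps": self.eps_history.min(axis=1),
                "max_eps": self.eps_history.max(axis=1),
            }
        )


def run_evolution(params: EvolutionParams, rng: np.random.Generator) -> EvolutionTrajectory:
    """Run S evolutionary steps from a common initial noise level eps0."""
    n, S = params.n, params.steps
    eps = np.full(n, float(params.eps0))
    eps_hist = np.empty((S + 1, n))
    pay_hist = np.empty((S, n))
    replaced = np.empty(S, dtype=int)
    copied = np.empty(S, dtype=int)
    eps_hist[0] = eps
    for s in range(S):
        scores = score_population(eps, params, rng)
        step = evolution_step(eps, scores, params.theta, rng)
        eps = step.eps
        eps_hist[s + 1] = eps
        pay_hist[s] = scores
        replaced[s] = step.replaced
        copied[s] = step.copied_from
    return EvolutionTrajectory(
        params=params,
        eps_history=eps_hist,
        payoff_history=pay_hist,
        replaced=replaced,
        copied_from=copied,
    )


def phase_diagram(
    alpha_grid,
    beta_grid,
    params: EvolutionParams,
    rng: np.random.Generator,
    reps: int = 40,
) -> pd.DataFrame:
    """Terminal mean noise level over an (alpha, beta) cost grid.

    Runs ``reps`` independent evolutionary runs per cell and averages the
    final group-mean eps.  Long-format output with one row per cell.
    """
    alpha_grid = np.atleast_1d(np.asarray(alpha_grid, dtype=float))
    beta_grid = np.atleast_1d(np.asarray(beta_grid, dtype=float))
    if alpha_grid.size == 0 or beta_grid.size == 0:
        raise ValueError("alpha and beta grids must be non-empty")
    rows = []
    for a in alpha_grid:
        for b in beta_grid:
            cell = EvolutionParams(
                n=params.n, k=params.k, tau=params.tau, alpha=float(a), beta=float(b),
                theta=params.theta, eps0=params.eps0, steps=params.steps,
                payoff_reps=params.payoff_reps, network=params.network,
            )
            finals = np.empty(reps)
            for r in range(reps):
                finals[r] = run_evolution(cell, rng).final_mean_eps
            rows.append((a, b, reps, finals.mean(), finals.std(ddof=1) if reps > 1 else 0.0))
    return pd.DataFrame(rows, columns=["alpha", "beta", "reps", "mean_final_eps", "sd_final_eps"])


def best_response_dynamics(
    eps_start: float,
    rng: np.random.Generator,
    alpha: float = 1.0,
    beta: float = 0.1,
    n: int = 10,
    k: int = 4,
    tau: int = 40,
    reps: int = 100,
    grid: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 0.0,
) -> np.ndarray:
    """Iterated best response of a common group noise level.

    Starting from a shared level eps_start, each iteration computes the
    focal agent's best-response eps* to the others' current level and moves
    the whole group there; stops when |eps_{m+1} - eps_m| <= tol (default:
    an exact grid fixed point) or after ``max_iter`` iterations.  Returns
    the sequence of group levels including the start.
    """
    seq = [float(eps_start)]
    for _ in range(max_iter):
        br = best_response_noise(
            seq[-1], alpha, beta, rng, grid=grid, n=n, k=k, tau=tau, reps=reps
        )
        seq.append(br.eps_star)
        if abs(seq[-1] - seq[-2]) <= tol:
            break
    return np.asarray(seq)
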