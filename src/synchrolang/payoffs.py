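"""Group and individual payoff accounting, best-response noise, group size.

The group earns C from the collective action, discounted by coordination
inefficiency: H = C - D*d_bar with D > 0.  Agent i's raw payoff is its share
of H minus an individual misalignment cost A*d_i and a precision cost
B*(180 - eps_i) (paying to keep reception noise low).  Normalising by D and
group size n gives

    h_i = -d_bar - alpha*d_i - beta*(180 - eps_i),

with alpha = n*A/D (cost of being individually out of line) and
beta = n*B/D (cost of communication precision).  Maximising h_i over eps_i
is equivalent to maximising the raw H_i, so the best-response analysis works
on h_i alone.

A survival threshold lambda on d_bar turns the group payoff into an
all-or-nothing c (C if d_bar <= lambda else 0), which defines the largest
group size n_max that can still coordinate at a given common noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SyncResult, sample_event
from .network import SocialNetwork

__all__ = [
    "PayoffParams",
    "BestResponse",
    "GroupSizeResult",
    "net_group_payoff",
    "individual_payoff",
    "event_payoffs",
    "best_response_noise",
    "max_group_size",
]


@dataclass(frozen=True)
class PayoffParams:
    """Cost parameters; either raw (C, D, A, B) or normalised (alpha, beta).

    ``lam`` is the survival threshold on d_bar (degrees), used only by the
    thresholded group payoff and the group-size search.
    """

    alpha: float = 1.0
    beta: float = 0.1
    C: float = 0.0
    D: float = 1.0
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.lam is not None and not (0.0 < self.lam <= 180.0):
            raise ValueError(f"lambda must lie in (0, 180], got {self.lam}")

    @classmethod
    def from_raw(cls, n: int, C: float, D: float, A: float, B: float, lam=None) -> "PayoffParams":
        if D <= 0:
            raise ValueError(f"D must be > 0, got {D}")
        return cls(alpha=n * A / D, beta=n * B / D, C=C, D=D, lam=lam)


def net_group_payoff(
    C: float, D: float, d_bar: float, lam: float | None = None
) -> tuple[float, float]:
    """Net group payoff (H, c).

    Without a threshold, c = C and H = C - D*d_bar.  With a survival
    threshold lam, c = C if d_bar <= lam (boundary inclusive) else 0, and
    H = c - D*d_bar.
    """
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    if not 0.0 <= d_bar <= 180.0:
        raise ValueError(f"d_bar must lie in [0, 180], got {d_bar}")
    c = C if lam is None or d_bar <= lam else 0.0
    return c - D * d_bar, c


def individual_payoff(d_bar, d_i, eps_i, alpha: float, beta: float):
    """Normalised individual payoff h_i = -d_bar - alpha*d_i - beta*(180 - eps_i).

    Accepts scalars or arrays for the distance/noise arguments.
    """
    d_bar = np.asarray(d_bar, dtype=float)
    d_i = np.asarray(d_i, dtype=float)
    eps_i = np.asarray(eps_i, dtype=float)
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    for name, v, hi in (("d_bar", d_bar, 180.0), ("d_i", d_i, 180.0), ("eps_i", eps_i, 180.0)):
        if np.any((v < 0) | (v > hi)):
            raise ValueError(f"{name} must lie in [0, {hi}]")
    out = -d_bar - alpha * d_i - beta * (180.0 - eps_i)
    return float(out) if out.ndim == 0 else out


def event_payoffs(result: SyncResult, noises, alpha: float, beta: float) -> np.ndarray:
    """Per-agent h_i for one synchronization event."""
    return individual_payoff(result.d_bar, result.d_i, noises, alpha, beta)


def _argbest(grid: np.ndarray, means: np.ndarray) -> int:
    """Index of the payoff-maximising candidate; ties go to the smallest eps."""
    order = np.argsort(grid, kind="stable")
    best = order[int(np.argmax(means[order]))]
    return int(best)


@dataclass(frozen=True)
class BestResponse:
    eps_star: float
    curve: pd.DataFrame = field(repr=False)  # columns: eps_candidate, mean_h_i, se, reps


def best_response_noise(
    eps_others: float,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
    n: int = 10,
    k: int = 4,
    tau: int = 40,
    reps: int = 100,
    focal: int = 0,
    network: SocialNetwork | None = None,
) -> BestResponse:
    """Grid best response of a focal agent's noise to a fixed group level.

    For each candidate eps on the grid, the focal agent adopts eps while all
    others stay at ``eps_others``; ``reps`` independent synchronization
    events are run and the focal agent's mean h_i recorded.  Common random
    numbers: the same per-replicate event seeds are reused for every
    candidate, so curve differences reflect the candidate alone.  Ties on
    the mean go to the smallest eps.
    """
    if grid is None:
        grid = np.arange(0.0, 181.0, 5.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("candidate grid must be non-empty")
    if np.any((grid < 0) | (grid > 180)):
        raise ValueError("candidate grid must lie within [0, 180]")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")

    rep_seeds = rng.integers(0, 2**31, size=reps)
    means = np.empty(grid.size)
    ses = np.empty(grid.size)
    for g, eps_c in enumerate(grid):
        noises = np.full(n, float(eps_others))
        noises[focal] = eps_c
        h = np.empty(reps)
        for r in range(reps):
            ev_rng = np.random.default_rng(rep_seeds[r])
            res = sample_event(n, k, tau, noises, ev_rng, network=network)
            h[r] = individual_payoff(res.d_bar, res.d_i[focal], eps_c, alpha, beta)
        means[g] = h.mean()
        ses[g] = h.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0

    curve = pd.DataFrame(
        {"eps_candidate": grid, "mean_h_i": means, "se": ses, "reps": reps}
    )
    return BestResponse(eps_star=float(grid[_argbest(grid, means)]), curve=curve)


@dataclass(frozen=True)
class GroupSizeResult:
    eps_common: float
    lam: float
    n_max: int | None
    censored: bool
    table: pd.DataFrame = field(repr=False)  # columns: n, mean_d_bar, se, feasible, survives


def max_group_size(
    eps_common: float,
    lam: float,
    rng: np.random.Generator,
    k: int = 4,
    tau: int = 40,
    n_range=range(5, 41),
    reps: int = 100,
) -> GroupSizeResult:
    """Largest group size whose mean d_bar stays within the survival threshold.

    Evaluates mean d_bar over ``reps`` events for each n in ascending
    ``n_range`` with every agent at ``eps_common``; n with no k-regular graph
    (n < k+1 or n*k odd) are recorded as infeasible and skipped.  Returns the
    largest surviving n; ``n_max is None`` if no n survives, and
    ``censored=True`` if the top of the range survives (the true maximum may
    lie beyond it).
    """
    if not 0.0 < lam <= 180.0:
        raise ValueError(f"lambda must lie in (0, 180], got {lam}")
    ns = sorted(int(n) for n in n_range)
    feasible_ns = [n for n in ns if n >= k + 1 and (n * k) % 2 == 0]
    if not feasible_ns:
        raise ValueError(f"no feasible group size in range for k={k}")

    rows = []
    for n in ns:
        feasible = n in set(feasible_ns)
        if not feasible:
            rows.append((n, np.nan, np.nan, False, False))
            continue
        d_bars = np.empty(reps)
        for r in range(reps):
            d_bars[r] = sample_event(n, k, tau, np.full(n, float(eps_common)), rng).d_bar
        mean = d_bars.mean()
        se = d_bars.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
        rows.append((n, mean, se, True, bool(mean <= lam)))
    table = pd.DataFrame(rows, columns=["n", "mean_d_bar", "se", "feasible", "survives"])

    surviving = table.loc[table["survives"], "n"]
    if surviving.empty:
        n_max, censored = None, False
    else:
        n_max = int(surviving.max())
        censored = n_max == max(feasible_ns)
    return GroupSizeResult(
        eps_common=float(eps_common), lam=float(lam), n_max=n_max, censored=censored, table=table
    )
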