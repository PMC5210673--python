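"""Circular-coordinate arithmetic and noisy pairwise synchronization events.

Agents hold headings on a dial (degrees, half-open [0, 360)).  A
synchronization event is T = tau*n/2 sequential pairwise meetings on the
social network: at each meeting both agents simultaneously reset their
heading to the midpoint (along the shorter arc) between their own heading
and the partner's heading as *perceived* through their own reception noise.
Reception noise for agent i is a two-point perturbation: the incoming
heading is shifted by +eps_i or -eps_i with equal probability, redrawn
independently at every meeting.

After the event, coordination quality is summarised by per-agent mean
circular distances d_i to all others and the group mean d_bar, both in
[0, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SocialNetwork, build_k_regular

__all__ = [
    "SyncParams",
    "SyncResult",
    "init_phases",
    "circular_midpoint",
    "circular_distance",
    "perceive",
    "do_meeting",
    "run_sync_event",
    "agent_distances",
    "sample_event",
]


def _wrap(x: float) -> float:
    # x % 360.0 can round to exactly 360.0 for tiny negative x
    r = x % 360.0
    return 0.0 if r == 360.0 else r


def circular_midpoint(phi_i: float, phi_j: float) -> float:
    """Midpoint of two headings along the shorter arc, wrapped into [0, 360).

    Three branches depending on the raw difference: plain average when
    |phi_i - phi_j| <= 180, otherwise the average shifted by ±180 so the
    result lies between the two headings on the short way round the dial.
    A raw difference of exactly 180 (antipodal headings) takes the plain
    average.
    """
    d = phi_i - phi_j
    if -180.0 <= d <= 180.0:
        f1 = (phi_i + phi_j) / 2.0
    elif d > 180.0:
        f1 = (phi_i + phi_j + 360.0) / 2.0
    else:  # d < -180
        f1 = (phi_i + phi_j - 360.0) / 2.0
    return _wrap(f1)


def circular_distance(a, b):
    """Shorter-arc angular distance in degrees, in [0, 180]. Vectorises."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def init_phases(n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent initial headings, uniform on [0, 360)."""
    if n < 1:
        raise ValueError(f"need n >= 1 agents, got {n}")
    return rng.uniform(0.0, 360.0, size=n)


def perceive(phi_sender: float, eps_receiver: float, rng: np.random.Generator) -> float:
    """The sender's heading as perceived through the receiver's noise.

    Returns (phi ± eps) wrapped to [0, 360); the sign is an independent fair
    coin flip per call.
    """
    if not 0.0 <= eps_receiver <= 180.0:
        raise ValueError(f"reception noise must lie in [0, 180], got {eps_receiver}")
    nu = eps_receiver if rng.integers(2) else -eps_receiver
    return _wrap(phi_sender + nu)


def do_meeting(
    phases: np.ndarray,
    i: int,
    j: int,
    noises: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meeting between agents i and j; returns the updated phase vector.

    Both agents update simultaneously from the pre-meeting headings:
    each moves to the midpoint between its own heading and the partner's
    heading perceived through its own reception noise.  All other agents
    are unchanged.
    """
    if i == j:
        raise ValueError("an agent cannot meet itself (i == j)")
    out = np.array(phases, dtype=float)
    perceived_j = perceive(phases[j], noises[i], rng)
    perceived_i = perceive(phases[i], noises[j], rng)
    out[i] = circular_midpoint(phases[i], perceived_j)
    out[j] = circular_midpoint(phases[j], perceived_i)
    return out


@dataclass(frozen=True)
class SyncParams:
    """Meeting schedule: tau exchanges per agent, i.e. T = tau*n/2 meetings."""

    tau: int = 40

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    def n_meetings(self, n: int) -> int:
        # round-to-nearest keeps T deterministic when tau*n is odd
        return int(round(self.tau * n / 2.0))


@dataclass(frozen=True)
class SyncResult:
    final_phases: np.ndarray
    d_i: np.ndarray
    d_bar: float


def agent_distances(phases: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-agent mean circular distance to all others, and the group mean.

    d_i averages the shorter-arc distance from agent i to every other agent;
    d_bar is the mean of the d_i.  Both lie in [0, 180].
    """
    ph = np.asarray(phases, dtype=float)
    n = ph.size
    if n < 2:
        raise ValueError(f"distances need at least 2 agents, got {n}")
    diff = np.abs(ph[:, None] - ph[None, :]) % 360.0
    dist = np.minimum(diff, 360.0 - diff)
    d_i = dist.sum(axis=1) / (n - 1)
    return d_i, float(d_i.mean())


def run_sync_event(
    network: SocialNetwork,
    phases0: np.ndarray,
    noises: np.ndarray,
    params: SyncParams,
    rng: np.random.Generator,
) -> SyncResult:
    """Run one synchronization event: T = tau*n/2 sequential meetings.

    Meetings are independent uniform draws over the network's edges; noise
    signs are independent fair coin flips per receiver per meeting.  Exact
    replay under an identical generator state.
    """
    n = network.n
    ph_arr = np.asarray(phases0, dtype=float)
    eps_arr = np.asarray(noises, dtype=float)
    if ph_arr.size != n or eps_arr.size != n:
        raise ValueError(
            f"size mismatch: network has {n} agents, phases {ph_arr.size}, noises {eps_arr.size}"
        )
    if np.any((eps_arr < 0) | (eps_arr > 180)):
        raise ValueError("all reception noises must lie in [0, 180]")

    T = params.n_meetings(n)
    ph = ph_arr.tolist()
    eps = eps_arr.tolist()
    if T > 0:
        edge_arr = network.edge_array()
        idx = rng.integers(0, edge_arr.shape[0], size=T)
        # sign of the perturbation for (receiver i, receiver j) at each meeting
        signs = rng.integers(0, 2, size=(T, 2)) * 2 - 1
        ii = edge_arr[idx, 0].tolist()
        jj = edge_arr[idx, 1].tolist()
        si = signs[:, 0].tolist()
        sj = signs[:, 1].tolist()
        for t in range(T):
            i = ii[t]
            j = jj[t]
            pi = ph[i]
            pj = ph[j]
            # i's perception of j, and vice versa (simultaneous update)
            qa = (pj + si[t] * eps[i]) % 360.0
            qb = (pi + sj[t] * eps[j]) % 360.0
            d = pi - qa
            if -180.0 <= d <= 180.0:
                ph[i] = ((pi + qa) / 2.0) % 360.0
            elif d > 180.0:
                ph[i] = ((pi + qa + 360.0) / 2.0) % 360.0
            else:
                ph[i] = ((pi + qa - 360.0) / 2.0) % 360.0
            d = pj - qb
            if -180.0 <= d <= 180.0:
                ph[j] = ((pj + qb) / 2.0) % 360.0
            elif d > 180.0:
                ph[j] = ((pj + qb + 360.0) / 2.0) % 360.0
            else:
                ph[j] = ((pj + qb - 360.0) / 2.0) % 360.0

    final = np.asarray(ph, dtype=float)
    final[final == 360.0] = 0.0  # guard the rare fmod rounding to exactly 360
    d_i, d_bar = agent_distances(final)
    return SyncResult(final_phases=final, d_i=d_i, d_bar=d_bar)


def sample_event(
    n: int,
    k: int,
    tau: int,
    noises: np.ndarray,
    rng: np.random.Generator,
    network: SocialNetwork | None = None,
) -> SyncResult:
    """Draw one complete synchronization event.

    Draws a fresh connected k-regular graph (unless a fixed ``network`` is
    supplied) and fresh uniform initial headings, then runs the event.
    """
    net = network if network is not None else build_k_regular(n, k, rng)
    phases0 = init_phases(n, rng)
    return run_sync_event(net, phases0, noises, SyncParams(tau), rng)
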