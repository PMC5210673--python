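"""Replace-worst evolutionary dynamics over noise levels."""

import numpy as np
import pytest

from synchrolang import (
    EvolutionParams,
    best_response_dynamics,
    evolution_step,
    phase_diagram,
    run_evolution,
    score_population,
)
from synchrolang.io import rng_substream


def test_step_theta_zero_copies_exactly(rng):
    eps = np.array([10.0, 40.0, 70.0])
    scores = np.array([-5.0, -1.0, -9.0])
    step = evolution_step(eps, scores, 0.0, rng)
    assert step.replaced == 2 and step.copied_from == 1
    assert step.eps.tolist() == [10.0, 40.0, 40.0]


def test_step_changes_exactly_one_agent(rng):
    eps = np.linspace(0, 180, 8)
    scores = rng.normal(size=8)
    step = evolution_step(eps, scores, 0.2, rng)
    changed = np.nonzero(step.eps != eps)[0]
    assert len(changed) <= 1 and step.replaced == int(np.argmin(scores))


def test_step_all_scores_equal_self_copy(rng):
    eps = np.array([50.0, 60.0, 70.0])
    step = evolution_step(eps, np.zeros(3), 0.1, rng)
    assert step.replaced == 0 and step.copied_from == 0
    assert 45.0 <= step.eps[0] <= 55.0  # redrawn around its own value
    assert step.eps[1] == 60.0 and step.eps[2] == 70.0


def test_step_mutation_support_and_clamp():
    rng = np.random.default_rng(0)
    eps = np.array([0.0, 170.0])
    scores = np.array([-1.0, 0.0])
    draws = np.array([evolution_step(eps, scores, 0.2, rng).eps[0] for _ in range(400)])
    # U(136, 204) clamped into [136, 180]
    assert draws.min() >= 136.0 and draws.max() <= 180.0
    assert (draws == 180.0).mean() > 0.2  # the clamped mass is visible
    assert (draws < 180.0).mean() > 0.2


def test_step_rejects_empty_and_mismatch(rng):
    with pytest.raises(ValueError):
        evolution_step(np.array([]), np.array([]), 0.1, rng)
    with pytest.raises(ValueError):
        evolution_step(np.array([1.0]), np.array([1.0, 2.0]), 0.1, rng)


def test_theta_zero_converges_within_n_minus_1_steps(rng):
    """With a strict, stable score ranking and no copying error, every agent
    ends up sharing the top agent's noise value within n-1 replacements."""
    n = 6
    eps = np.linspace(10.0, 160.0, n)
    fixed_scores = -eps  # lower noise always scores higher
    for _ in range(n - 1):
        step = evolution_step(eps, fixed_scores, 0.0, rng)
        eps = step.eps
        fixed_scores = fixed_scores.copy()
        fixed_scores[step.replaced] = fixed_scores[step.copied_from]
    assert np.unique(eps).size == 1
    assert eps[0] == 10.0


def test_score_population_single_event_replay():
    """payoff_reps=1 scoring equals the h_i of the one underlying event."""
    from synchrolang.core import sample_event
    from synchrolang.payoffs import event_payoffs

    params = EvolutionParams(payoff_reps=1)
    eps = np.full(10, 25.0)
    scores = score_population(eps, params, np.random.default_rng(5))
    # replay the single event with the same derived stream
    rng = np.random.default_rng(5)
    res = sample_event(10, 4, 40, eps, rng)
    np.testing.assert_allclose(scores, event_payoffs(res, eps, params.alpha, params.beta))


def test_symmetric_agents_score_alike():
    """On a vertex-transitive ring with equal noise, mean payoffs are
    statistically indistinguishable across agents (within 3 SE, 400 events)."""
    from synchrolang.core import sample_event
    from synchrolang.network import SocialNetwork
    from synchrolang.payoffs import event_payoffs

    n = 6
    ring = SocialNetwork.from_edges(n, [(i, (i + 1) % n) for i in range(n)])
    rng = np.random.default_rng(9)
    eps = np.full(n, 30.0)
    h = np.array(
        [
            event_payoffs(sample_event(n, 2, 40, eps, rng, network=ring), eps, 1.0, 0.1)
            for _ in range(400)
        ]
    )
    means = h.mean(axis=0)
    se = h.std(axis=0, ddof=1) / np.sqrt(h.shape[0])
    grand = means.mean()
    assert np.all(np.abs(means - grand) < 3 * se)


def test_higher_own_noise_worsens_own_alignment():
    """Raising one agent's reception noise (others fixed) raises that agent's
    mean distance to the group."""
    from synchrolang.core import sample_event

    def mean_focal_d(eps_focal, seed_base):
        vals = []
        for s in range(200):
            eps = np.full(10, 10.0)
            eps[0] = eps_focal
            res = sample_event(10, 4, 40, eps, np.random.default_rng(seed_base + s))
            vals.append(res.d_i[0])
        return np.mean(vals)

    assert mean_focal_d(60.0, 0) > mean_focal_d(10.0, 0)


def test_run_evolution_zero_steps_and_replay():
    params = EvolutionParams(steps=0, eps0=20.0)
    traj = run_evolution(params, np.random.default_rng(1))
    assert traj.eps_history.shape == (1, 10)
    assert traj.final_mean_eps == 20.0

    params = EvolutionParams(steps=30)
    a = run_evolution(params, rng_substream(3, 0))
    b = run_evolution(params, rng_substream(3, 0))
    np.testing.assert_array_equal(a.eps_history, b.eps_history)
    np.testing.assert_array_equal(a.replaced, b.replaced)


def test_run_evolution_bounds_and_records(rng):
    params = EvolutionParams(steps=50, theta=0.3, eps0=170.0)
    traj = run_evolution(params, rng)
    assert np.all((traj.eps_history >= 0) & (traj.eps_history <= 180))
    assert traj.eps_history.shape == (51, 10)
    assert traj.payoff_history.shape == (50, 10)
    frame = traj.to_frame()
    assert set(frame.columns) == {
        "step", "agent_id", "eps", "h_i", "replaced_flag", "copied_from"
    }
    assert frame.replaced_flag.sum() == 50  # one replacement per step


def test_terminal_regime_depends_on_cost_ratio_only():
    """Scaling (alpha, beta) together leaves the evolutionary endpoint
    unchanged: both (1, 10) and (2, 20) collapse to the same high-noise
    state."""
    finals = {}
    for scale in (1.0, 2.0):
        params = EvolutionParams(alpha=scale, beta=10.0 * scale, steps=600, payoff_reps=1)
        finals[scale] = np.mean(
            [run_evolution(params, rng_substream(21, 10 * int(scale) + r)).final_mean_eps
             for r in range(6)]
        )
    assert finals[1.0] > 150 and finals[2.0] > 150
    assert abs(finals[1.0] - finals[2.0]) < 15


def test_phase_diagram_regimes_and_shape():
    params = EvolutionParams(steps=500, payoff_reps=3)
    table = phase_diagram([1.0], [0.1, 10.0], params, rng_substream(31, 0), reps=3)
    assert list(table.columns) == ["alpha", "beta", "reps", "mean_final_eps", "sd_final_eps"]
    assert len(table) == 2
    low = table.loc[table.beta == 0.1, "mean_final_eps"].item()
    high = table.loc[table.beta == 10.0, "mean_final_eps"].item()
    assert low < high  # cheap precision keeps noise down; dear precision collapses


def test_best_response_dynamics_fixed_point():
    """A group already at the optimum never moves: the sequence is constant
    and stops immediately."""
    seq = best_response_dynamics(0.0, rng_substream(41, 0), reps=60)
    assert len(seq) <= 2
    assert np.all(seq == 0.0)


def test_best_response_dynamics_descends_gradually():
    """From a moderately noisy start the group walks down to fluency; the
    best response never overshoots above the group's current level."""
    seq = best_response_dynamics(60.0, rng_substream(42, 0), reps=60)
    assert np.all(np.diff(seq) <= 0)
    assert seq[-1] < 10.0
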