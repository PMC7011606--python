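"""Ground-truth behavioral simulator of a child responding to robot actions.

A :class:`ChildProfile` holds the true transition tensor ``P*[state, action,
next_state]`` governing how the simulated child's interaction mode changes
in response to each robot maneuver, plus a dwell-time model. The simulator
supports two kinds of experiments:

* *parameter recovery* — how well the maximum-likelihood and smoothed
  estimators reconstruct ``P*`` from limited observations, and
* *policy comparison* — whether the model-optimal robot policy collects
  utility faster than the human-operator baseline, session for session.

The fixture profiles shipped here (``responsive_child``,
``distractible_child``) are synthetic: their parameters are design choices,
not calibrated to any real subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cri_mdp import (
    ACTIONS,
    DEFAULT_UTILITIES,
    STATES,
    CriMdp,
    Episode,
    EpisodeRecord,
    Policy,
    TransitionCounts,
    accumulate_utility,
    defined_rows,
    estimate_ml,
    estimate_smoothed,
    state_index,
    update_counts,
)

__all__ = [
    "ChildProfile",
    "simulate_episode",
    "recovery_experiment",
    "compare_policies",
    "expected_utility_rate",
    "responsive_child",
    "distractible_child",
]


@dataclass
class ChildProfile:
    """Ground-truth child model: transition tensor plus timing.

    Parameters
    ----------
    true_transition:
        Row-stochastic tensor ``P*[state, action, next_state]`` of shape
        (4, 3, 4).
    dwell_s:
        Mean time between child transitions, in seconds (exponential
        inter-transition times).
    drift:
        Optional per-session multiplicative perturbation factor applied to
        the off-diagonal mass of ``P*`` (re-normalized); ``None`` disables
        session-to-session drift.
    """

    true_transition: np.ndarray
    dwell_s: float = 2.0
    drift: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_transition = np.asarray(self.true_transition, dtype=float)
        expected = (len(STATES), len(ACTIONS), len(STATES))
        if self.true_transition.shape != expected:
            raise ValueError(f"transition tensor must have shape {expected}")
        if (self.true_transition < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        rows = self.true_transition.reshape(-1, len(STATES))
        if (np.abs(rows.sum(axis=1) - 1.0) > 1e-9).any():
            raise ValueError("every (state, action) row of P* must sum to 1")
        if self.dwell_s <= 0:
            raise ValueError("dwell time must be positive")

    def drifted(self, session: int) -> "ChildProfile":
        """Profile for a later session with multiplicative drift applied."""
        if self.drift is None or session == 0:
            return self
        P = self.true_transition.copy()
        factor = self.drift**session
        for s in range(len(STATES)):
            off = np.arange(len(STATES)) != s
            P[s, :, off] *= factor
            P[s] /= P[s].sum(axis=1, keepdims=True)
        return ChildProfile(P, self.dwell_s, None, self.seed)

    def as_mdp(self, utility=DEFAULT_UTILITIES) -> CriMdp:
        return CriMdp(self.true_transition.copy(), np.asarray(utility, float))


def simulate_episode(
    profile: ChildProfile,
    policy: Policy,
    duration_s: float,
    seed: int,
    start_state: str = "NL",
) -> Episode:
    """Simulate one play session under a fixed robot policy.

    The robot applies ``policy`` at the child's current state; after an
    exponential dwell time the child transitions according to
    ``P*[state, action, .]``. The episode log records each transition with
    its timestamp, robot action, and the state entered.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    records: list[EpisodeRecord] = []
    state = state_index(start_state)
    t = 0.0
    n_states = len(STATES)
    while True:
        t += rng.exponential(profile.dwell_s)
        if t >= duration_s:
            break
        action = policy.action(STATES[state])
        a = ACTIONS.index(action)
        state = rng.choice(n_states, p=profile.true_transition[state, a])
        records.append(EpisodeRecord(t, action, STATES[state]))
    return Episode(records, duration_s, start_state=start_state)


def _uniform_exploration_counts(
    profile: ChildProfile, n_transitions: int, rng: np.random.Generator
) -> TransitionCounts:
    # Robot actions drawn uniformly over {f, s, b}: guarantees (eventual)
    # coverage of every (state, action) row.
    counts = TransitionCounts()
    state = 0  # NL
    for _ in range(n_transitions):
        a = rng.integers(len(ACTIONS))
        nxt = rng.choice(len(STATES), p=profile.true_transition[state, a])
        update_counts(counts, STATES[state], ACTIONS[a], STATES[nxt])
        state = nxt
    return counts


def recovery_experiment(
    profile: ChildProfile,
    n_transitions: int,
    estimator: str = "smoothed",
    lam: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit an estimator to simulated data and measure recovery of ``P*``.

    Simulates ``n_transitions`` child responses under a uniformly exploring
    robot, fits the chosen estimator (``"ml"`` or ``"smoothed"``), and
    reports one row per (state, action) pair with the total-variation
    distance to the ground-truth row. ML rows with no observations have
    ``defined == False`` and NaN distance.
    """
    if n_transitions < 1:
        raise ValueError("need at least one transition")
    rng = np.random.default_rng(seed)
    counts = _uniform_exploration_counts(profile, n_transitions, rng)
    if estimator == "ml":
        P_hat = estimate_ml(counts)
    elif estimator == "smoothed":
        P_hat = estimate_smoothed(counts, lam)
    else:
        raise ValueError("estimator must be 'ml' or 'smoothed'")
    mask = defined_rows(P_hat)
    rows = []
    for s, state in enumerate(STATES):
        for a, action in enumerate(ACTIONS):
            tv = 0.5 * np.abs(P_hat[s, a] - profile.true_transition[s, a]).sum()
            rows.append(
                {
                    "state": state,
                    "action": action,
                    "n_obs": int(counts.counts[s, a].sum()),
                    "defined": bool(mask[s, a]),
                    "total_variation": float(tv) if mask[s, a] else np.nan,
                }
            )
    return pd.DataFrame(rows)


def compare_policies(
    profile: ChildProfile,
    policy_a: Policy,
    policy_b: Policy,
    duration_s: float = 180.0,
    n_reps: int = 100,
    seed: int = 0,
    utility=DEFAULT_UTILITIES,
) -> dict:
    """Monte-Carlo comparison of two robot policies on the same child.

    Runs ``n_reps`` paired, seeded sessions per policy and scores each with
    the time-normalized accumulated utility. Returns the mean difference
    (b - a), its standard deviation, the per-replicate rates, and the
    fraction of replicates in which policy b did at least as well.
    """
    root = np.random.default_rng(seed)
    # paired replicates: same episode seed for both policies
    rep_seeds = root.integers(0, 2**31 - 1, size=n_reps)
    rates_a = np.array(
        [
            accumulate_utility(simulate_episode(profile, policy_a, duration_s, s), utility)
            for s in rep_seeds
        ]
    )
    rates_b = np.array(
        [
            accumulate_utility(simulate_episode(profile, policy_b, duration_s, s), utility)
            for s in rep_seeds
        ]
    )
    diff = rates_b - rates_a
    return {
        "mean_difference": float(diff.mean()),
        "std_difference": float(diff.std(ddof=1)) if n_reps > 1 else 0.0,
        "rates_a": rates_a,
        "rates_b": rates_b,
        "fraction_b_ge_a": float((diff >= 0).mean()),
    }


def expected_utility_rate(
    profile: ChildProfile, policy: Policy, utility=DEFAULT_UTILITIES
) -> float:
    """Closed-form long-run utility per second of a policy on a child.

    The policy-induced chain's stationary distribution gives the expected
    utility collected per transition; dividing by the mean dwell time turns
    it into a rate per second.
    """
    u = np.asarray(list(utility), dtype=float)
    acts = policy.action_indices()
    idx = np.arange(len(STATES))
    P_pi = profile.true_transition[idx, acts, :]
    # stationary distribution: left eigenvector of P_pi for eigenvalue 1
    vals, vecs = np.linalg.eig(P_pi.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()
    return float(pi @ P_pi @ u / profile.dwell_s)


def responsive_child(dwell_s: float = 2.0, seed: int = 0) -> ChildProfile:
    """Synthetic fixture: a child who engages when the robot plays it right.

    Retreating (b) while the child is moving strongly sustains the chase;
    staying put (s) while the child is looking tends to produce touching /
    arousal; approaching (f) mostly resets attention to looking. Parameters
    are synthetic design choices, not measurements.
    """
    P = np.empty((4, 3, 4))
    #                 NL     L     T/A    M
    P[0] = [
        [0.30, 0.55, 0.05, 0.10],  # f: approaching attracts attention
        [0.75, 0.20, 0.02, 0.03],  # s: mostly stays oblivious
        [0.80, 0.15, 0.02, 0.03],  # b
    ]
    P[1] = [
        [0.35, 0.40, 0.15, 0.10],  # f: often startles back toward NL
        [0.05, 0.15, 0.60, 0.20],  # s: looking ripens into touch/arousal
        [0.10, 0.30, 0.10, 0.50],  # b: retreat invites a chase
    ]
    P[2] = [
        [0.25, 0.35, 0.30, 0.10],  # f
        [0.05, 0.15, 0.60, 0.20],  # s: holds the engagement
        [0.05, 0.15, 0.20, 0.60],  # b: backing off converts touch into chase
    ]
    P[3] = [
        [0.30, 0.30, 0.10, 0.30],  # f: closing in breaks the chase
        [0.15, 0.25, 0.15, 0.45],  # s
        [0.03, 0.07, 0.05, 0.85],  # b: keeps the chase going
    ]
    return ChildProfile(P, dwell_s=dwell_s, seed=seed)


def distractible_child(dwell_s: float = 2.0, seed: int = 0) -> ChildProfile:
    """Synthetic fixture: a child whose attention decays quickly to NL."""
    P = np.empty((4, 3, 4))
    P[0] = [
        [0.60, 0.30, 0.04, 0.06],
        [0.85, 0.10, 0.02, 0.03],
        [0.85, 0.10, 0.02, 0.03],
    ]
    P[1] = [
        [0.55, 0.25, 0.10, 0.10],
        [0.45, 0.25, 0.20, 0.10],
        [0.45, 0.25, 0.10, 0.20],
    ]
    P[2] = [
        [0.50, 0.25, 0.15, 0.10],
        [0.40, 0.25, 0.25, 0.10],
        [0.40, 0.20, 0.15, 0.25],
    ]
    P[3] = [
        [0.55, 0.20, 0.05, 0.20],
        [0.45, 0.20, 0.10, 0.25],
        [0.35, 0.15, 0.05, 0.45],
    ]
    return ChildProfile(P, dwell_s=dwell_s, seed=seed)
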