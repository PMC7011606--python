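"""Markov decision process for play-based child-robot interaction.

The robot plays a chasing game with a young child. At any moment the child
is in one of four interaction modes:

* ``NL`` — not looking at the robot,
* ``L``  — looking at the robot but not following it,
* ``T/A`` — touching the robot, or visibly aroused (e.g. clapping),
* ``M``  — moving toward / following the robot.

The robot chooses among three maneuvers:

* ``f`` — move forward, toward the child,
* ``s`` — stay in place (or turn without changing distance),
* ``b`` — retreat while facing the child.

Transitions of the child's mode in response to a robot maneuver define an
MDP.  Per-state utilities (default ``(0, 0, 1, 2)``) reward touching/arousal
and, above all, movement.  Transition probabilities are unknown a priori and
must be estimated from very few supervised observations, which motivates two
estimators: plain maximum likelihood, and additive (add-``lambda``)
smoothing that keeps every transition possible.  An event not yet observed
is not necessarily impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

STATES: tuple[str, ...] = ("NL", "L", "T/A", "M")
ACTIONS: tuple[str, ...] = ("f", "s", "b")
DEFAULT_UTILITIES: tuple[float, ...] = (0.0, 0.0, 1.0, 2.0)

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_ACTION_INDEX = {a: i for i, a in enumerate(ACTIONS)}

# "TA" is the file-format spelling of the slash-containing state name.
_STATE_ALIASES = {"TA": "T/A"}


def state_index(state: str) -> int:
    """Map a state symbol (``"TA"`` accepted as an alias of ``"T/A"``) to its index."""
    state = _STATE_ALIASES.get(state, state)
    try:
        return _STATE_INDEX[state]
    except KeyError:
        raise ValueError(
            f"unknown child state {state!r}; expected one of {STATES}"
        ) from None


def action_index(action: str) -> int:
    try:
        return _ACTION_INDEX[action]
    except KeyError:
        raise ValueError(
            f"unknown robot action {action!r}; expected one of {ACTIONS}"
        ) from None


@dataclass
class TransitionCounts:
    """Integer tensor ``N[state, action, next_state]`` of observed transitions.

    This is the sufficient statistic for both transition estimators. Counts
    only ever grow under online updates.
    """

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(
            (len(STATES), len(ACTIONS), len(STATES)), dtype=np.int64
        )
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = (len(STATES), len(ACTIONS), len(STATES))
        if self.counts.shape != expected:
            raise ValueError(f"counts tensor must have shape {expected}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def copy(self) -> "TransitionCounts":
        return TransitionCounts(self.counts.copy())


def update_counts(
    counts: TransitionCounts, from_state: str, action: str, to_state: str
) -> TransitionCounts:
    """Record one observed transition; increments exactly one cell in place.

    Returns the same ``TransitionCounts`` object for chaining.
    """
    i, a, j = state_index(from_state), action_index(action), state_index(to_state)
    counts.counts[i, a, j] += 1
    return counts


def counts_from_episode(episode: "Episode") -> TransitionCounts:
    """Accumulate transition counts from an episode's records.

    Each record documents the child's new state after a robot action; the
    originating state is the previous record's state (the first record's
    originating state is the episode's ``start_state``).
    """
    counts = TransitionCounts()
    prev = episode.start_state
    for record in episode.records:
        update_counts(counts, prev, record.robot_action, record.child_state)
        prev = record.child_state
    return counts


def estimate_ml(counts: TransitionCounts) -> np.ndarray:
    """Maximum-likelihood transition tensor, ``P = N / row-total``.

    Rows with zero observations are *undefined* and returned as NaN —
    deliberately distinct from a uniform default, so that planning on
    unobserved state-action pairs fails loudly until smoothing is applied.
    """
    N = counts.counts.astype(float)
    totals = N.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = N / totals
    P[np.broadcast_to(totals == 0, P.shape)] = np.nan
    return P


def estimate_smoothed(counts: TransitionCounts, lam: float = 1.0) -> np.ndarray:
    """Additive (add-``lam``) smoothing of the transition tensor.

    ``P[s,a,k] = (N[s,a,k] + lam) / (sum_j N[s,a,j] + lam * |states|)``.
    Every entry is strictly positive and every row sums to one, so unseen
    transitions keep a small but nonzero probability.
    """
    if lam <= 0:
        raise ValueError("smoothing parameter lambda must be > 0")
    N = counts.counts.astype(float)
    totals = N.sum(axis=2, keepdims=True)
    return (N + lam) / (totals + lam * len(STATES))


def defined_rows(transition: np.ndarray) -> np.ndarray:
    """Boolean mask over (state, action) pairs whose rows are defined (no NaN)."""
    return ~np.isnan(transition).any(axis=2)


@dataclass(frozen=True)
class Policy:
    """Deterministic stationary policy: one robot action per child state."""

    mapping: Mapping[str, str]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        missing = [s for s in STATES if s not in self.mapping]
        if missing:
            raise ValueError(f"policy must cover all states; missing {missing}")
        for s, a in self.mapping.items():
            state_index(s)
            action_index(a)

    def action(self, state: str) -> str:
        return self.mapping[_STATE_ALIASES.get(state, state)]

    def action_indices(self) -> np.ndarray:
        return np.array([action_index(self.mapping[s]) for s in STATES])


def regular_policy() -> Policy:
    """The human-operator baseline strategy, as a fixed policy.

    Interpretation of the operators' narrative strategy: approach a child who
    is not engaging in the activity (states NL and L), hold position while
    the child is touching/aroused, and retreat when the child gives chase so
    as to steer them along.
    """
    return Policy(
        {"NL": "f", "L": "f", "T/A": "s", "M": "b"}, provenance="regular"
    )


@dataclass
class CriMdp:
    """The child-robot-interaction MDP: states, actions, transitions, utilities."""

    transition: np.ndarray
    utility: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_UTILITIES)
    )

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.utility = np.asarray(self.utility, dtype=float)
        expected = (len(STATES), len(ACTIONS), len(STATES))
        if self.transition.shape != expected:
            raise ValueError(f"transition tensor must have shape {expected}")
        if self.utility.shape != (len(STATES),):
            raise ValueError("utility vector must have one entry per state")
        mask = defined_rows(self.transition)
        rows = self.transition[mask]
        if rows.size and (
            (rows < -1e-12).any()
            or (np.abs(rows.sum(axis=1) - 1.0) > 1e-9).any()
        ):
            raise ValueError("defined transition rows must be stochastic")

    def expected_reward(self) -> np.ndarray:
        """One-step expected utility ``R[s,a] = sum_k P[s,a,k] * u[k]``.

        Utility is collected on *entering* a state.
        """
        return np.einsum("sak,k->sa", self.transition, self.utility)


def value_iteration(
    mdp: CriMdp, gamma: float = 0.95, tol: float = 1e-8, max_iter: int = 100_000
) -> tuple[Policy, np.ndarray]:
    """Optimal policy and state values by Bellman value iteration.

    Requires every transition row to be defined; fit with
    :func:`estimate_smoothed` first when observations are sparse. Greedy
    ties break toward the earlier action in the fixed order ``(f, s, b)``.
    """
    if not 0 <= gamma < 1:
        raise ValueError("gamma must lie in [0, 1)")
    if not defined_rows(mdp.transition).all():
        raise ValueError(
            "transition tensor has undefined (unobserved) rows; "
            "use estimate_smoothed to obtain a fully defined model"
        )
    R = mdp.expected_reward()
    P = mdp.transition
    V = np.zeros(len(STATES))
    for _ in range(max_iter):
        Q = R + gamma * np.einsum("sak,k->sa", P, V)
        V_new = Q.max(axis=1)
        if np.abs(V_new - V).max() < tol:
            V = V_new
            break
        V = V_new
    Q = R + gamma * np.einsum("sak,k->sa", P, V)
    greedy = Q.argmax(axis=1)  # argmax takes the first maximizer: fixed-order ties
    mapping = {s: ACTIONS[a] for s, a in zip(STATES, greedy)}
    return Policy(mapping, provenance="optimal"), V


def evaluate_policy(mdp: CriMdp, policy: Policy, gamma: float = 0.95) -> np.ndarray:
    """Exact discounted value of a fixed policy, by solving the linear system.

    ``V = R_pi + gamma * P_pi V``; used as the exhaustive-enumeration oracle
    against which the greedy planner can be checked.
    """
    acts = policy.action_indices()
    idx = np.arange(len(STATES))
    P_pi = mdp.transition[idx, acts, :]
    R_pi = mdp.expected_reward()[idx, acts]
    return np.linalg.solve(np.eye(len(STATES)) - gamma * P_pi, R_pi)


def enumerate_policies() -> list[Policy]:
    """All |A|^|S| = 81 deterministic stationary policies."""
    policies = []
    n = len(ACTIONS)
    for code in range(n ** len(STATES)):
        mapping = {}
        c = code
        for s in STATES:
            mapping[s] = ACTIONS[c % n]
            c //= n
        policies.append(Policy(mapping))
    return policies


@dataclass(frozen=True)
class EpisodeRecord:
    timestamp_s: float
    robot_action: str
    child_state: str


@dataclass
class Episode:
    """Timestamped record of one interaction session.

    Each record logs the child's state entered at that time, as a response
    to the logged robot action. ``start_state`` is the child's state at
    session start (before any logged transition).
    """

    records: Sequence[EpisodeRecord]
    duration_s: float
    start_state: str = "NL"

    def __post_init__(self) -> None:
        times = [r.timestamp_s for r in self.records]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("episode timestamps must be strictly increasing")
        if times and self.duration_s < times[-1]:
            raise ValueError("episode duration must cover the last timestamp")
        state_index(self.start_state)
        for r in self.records:
            state_index(r.child_state)
            action_index(r.robot_action)

    @property
    def n_transitions(self) -> int:
        return len(self.records)


def accumulate_utility(
    episode: Episode, utility: Iterable[float] = DEFAULT_UTILITIES
) -> float:
    """Session score: total utility of the states entered, per second.

    Sums the per-state utility over the episode's recorded state entries and
    normalizes by session duration, so sessions of different lengths are
    comparable.
    """
    u = np.asarray(list(utility), dtype=float)
    if u.shape != (len(STATES),):
        raise ValueError("utility vector must have one entry per state")
    if not episode.records:
        raise ValueError("episode has no recorded transitions")
    if episode.duration_s <= 0:
        raise ValueError("episode duration must be positive")
    total = sum(u[state_index(r.child_state)] for r in episode.records)
    return float(total / episode.duration_s)


def policy_change_score(
    episode_first: Episode,
    episode_last: Episode,
    utility: Iterable[float] = DEFAULT_UTILITIES,
) -> float:
    """Absolute change in time-normalized accumulated utility between sessions."""
    u = list(utility)
    return abs(
        accumulate_utility(episode_last, u) - accumulate_utility(episode_first, u)
    )
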