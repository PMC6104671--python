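"""The child learner: token store, interaction step and forgetting.

The child's lexical knowledge is a grid of integer token counts
``c(r, w)`` — accumulated evidence that word ``w`` labels referent ``r``.
Each adult-child interaction shows the child one word in the presence of
two referents (one intended target, one incidental distractor) and
deposits one token in each of the two referent-word slots.  The child's
probabilistic lexicon is the row-normalized token grid
``C(r, w) = c(r, w) / n(r)``, where ``n(r)`` counts the tokens currently
remembered for referent ``r``; forgetting removes tokens (and with them
the memory of the occurrence), so ``n(r)`` always equals the row sum of
``c``.

Two forgetting mechanisms oppose token accumulation:

* **naive** — every ``m`` iterations, one token is removed from every
  non-zero slot.  The per-slot loss rate ``1/m`` is independent of the
  slot's count, so rarely-reinforced (noise) slots are wiped while
  frequently-reinforced (signal) slots keep growing whenever their token
  arrival rate exceeds ``1/m``.
* **Ebbinghaus** — each token independently survives each timestep with
  probability ``1 - d(r, w)``, where the per-token deletion rate decays
  exponentially with the slot's *relative* repetition count (the fraction
  of all tokens ever heard that landed in this slot).  Newly encountered
  associations are forgotten at the initial rate ``1/d0``; once a slot
  accounts for a fraction ``d1`` of total experience its rate has dropped
  to ``e**-1`` (~36%) of that.

The cumulative repetition counters ``N_rw`` and ``N`` are never
decremented: they record everything the child has ever heard and drive
the Ebbinghaus rate only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .lexicon import Population

__all__ = [
    "ChildState",
    "NoForgetting",
    "NaiveForgetting",
    "EbbinghausForgetting",
    "ForgettingPolicy",
    "InteractionEvent",
    "child_probabilities",
    "interaction_step",
    "apply_naive_forgetting",
    "apply_ebbinghaus_forgetting",
    "apply_forgetting",
    "ebbinghaus_rate",
]


# ---------------------------------------------------------------------------
# Forgetting policies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoForgetting:
    """Unbounded memory: tokens are never removed."""

    kind = "none"


@dataclass(frozen=True)
class NaiveForgetting:
    """Remove one token from every non-zero slot every ``m`` iterations."""

    m: int

    kind = "naive"

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError(f"memory parameter m must be an integer >= 1, got {self.m!r}")


@dataclass(frozen=True)
class EbbinghausForgetting:
    """Stochastic per-token decay with repetition-dependent rate.

    Parameters
    ----------
    d0_inv : float
        Initial per-token per-timestep deletion probability ``1/d0`` for a
        just-encountered association; must lie in (0, 1].
    d1 : float
        Relative-repetition scale: at ``N_rw / N = d1`` the deletion rate
        has dropped to ``e**-1`` of ``d0_inv``.  Must be positive.
    """

    d0_inv: float = 0.01
    d1: float = 0.01

    kind = "ebbinghaus"

    def __post_init__(self) -> None:
        if not (0.0 < self.d0_inv <= 1.0):
            raise ValueError(f"d0_inv must lie in (0, 1], got {self.d0_inv!r}")
        if not (self.d1 > 0.0):
            raise ValueError(f"d1 must be positive, got {self.d1!r}")


ForgettingPolicy = Union[NoForgetting, NaiveForgetting, EbbinghausForgetting]


# ---------------------------------------------------------------------------
# Child state
# ---------------------------------------------------------------------------

@dataclass
class ChildState:
    """Mutable token store of a single learner.

    Attributes
    ----------
    c : (R, W) int array
        Surviving token counts per referent-word slot.
    n : (R,) int array
        Remembered occurrence count per referent; invariantly the row sum
        of ``c`` (forgetting removes the occurrence along with the token).
    n_rep : (R, W) int array
        Cumulative repetitions ``N_rw``: tokens ever added, never removed.
    n_total : int
        ``N = sum(N_rw)``.
    t : int
        Iteration clock (one adult-child interaction per tick).
    """

    c: np.ndarray
    n: np.ndarray
    n_rep: np.ndarray
    n_total: int
    t: int

    @classmethod
    def fresh(cls, n_referents: int, n_words: int) -> "ChildState":
        """A newborn learner with no associations."""
        return cls(
            c=np.zeros((n_referents, n_words), dtype=np.int64),
            n=np.zeros(n_referents, dtype=np.int64),
            n_rep=np.zeros((n_referents, n_words), dtype=np.int64),
            n_total=0,
            t=0,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.c.shape

    def copy(self) -> "ChildState":
        return ChildState(self.c.copy(), self.n.copy(), self.n_rep.copy(),
                          self.n_total, self.t)

    def check_invariants(self) -> None:
        """Raise AssertionError if any count invariant is violated."""
        assert np.all(self.c >= 0), "negative token count"
        assert np.all(self.n_rep >= 0), "negative repetition count"
        assert np.all(self.c <= self.n_rep), "c exceeds cumulative repetitions"
        assert self.n_total == int(self.n_rep.sum()), "N != sum(N_rw)"
        assert np.array_equal(self.n, self.c.sum(axis=1)), "n != row sums of c"
        assert np.all(self.n <= self.n_rep.sum(axis=1)), "n exceeds row repetitions"


@dataclass(frozen=True)
class InteractionEvent:
    """Record of one adult-child interaction (all indices 0-based)."""

    t: int
    adult: int
    target: int
    distractor: int
    word: int


def child_probabilities(state: ChildState) -> np.ndarray:
    """The child's probabilistic lexicon ``C(r, w) = c(r, w) / n(r)``.

    Rows with no remembered occurrences are all-zero; non-empty rows sum
    to 1 by construction.
    """
    n = state.n[:, None]
    return np.divide(state.c, n, out=np.zeros(state.c.shape, dtype=float),
                     where=n > 0)


# ---------------------------------------------------------------------------
# One interaction
# ---------------------------------------------------------------------------

def _draw_referent_pair(
    n_referents: int,
    rng: np.random.Generator,
    referent_weights: Optional[np.ndarray],
) -> tuple[int, int]:
    if referent_weights is None:
        r1 = int(rng.integers(n_referents))
        r2 = int((r1 + 1 + rng.integers(n_referents - 1)) % n_referents)
        return r1, r2
    w = np.asarray(referent_weights, dtype=float)
    if w.shape != (n_referents,) or np.any(w < 0):
        raise ValueError("referent weights must be non-negative with one entry per referent")
    if np.count_nonzero(w) < 2:
        raise ValueError("referent distribution must put mass on at least 2 referents")
    p = w / w.sum()
    cdf = np.cumsum(p)
    r1 = int(np.searchsorted(cdf, rng.random(), side="right"))
    while True:  # rejection: without-replacement second draw
        r2 = int(np.searchsorted(cdf, rng.random(), side="right"))
        if r2 != r1:
            return r1, r2


def interaction_step(
    state: ChildState,
    pop: Population,
    rng: np.random.Generator,
    referent_weights: Optional[np.ndarray] = None,
) -> InteractionEvent:
    """Run one usage event, mutating ``state`` in place.

    An adult is chosen uniformly from the population; two distinct
    referents are drawn (target ``R1`` and distractor ``R2``, uniformly by
    default); the adult utters a word from its distribution for ``R1``;
    the child records one token against each referent.  Forgetting is a
    separate operation (see :func:`apply_forgetting`).

    Returns the event record; the updated state is ``state`` itself.
    """
    n_ref, _ = pop.shape
    r1, r2 = _draw_referent_pair(n_ref, rng, referent_weights)
    j = int(rng.integers(pop.n_adults)) if pop.n_adults > 1 else 0
    row = pop.adults[j].probs[r1]
    cdf = np.cumsum(row)
    cdf[-1] = 1.0  # guard against float round-off in the last bin
    word = int(np.searchsorted(cdf, rng.random(), side="right"))

    state.c[r1, word] += 1
    state.c[r2, word] += 1
    state.n[r1] += 1
    state.n[r2] += 1
    state.n_rep[r1, word] += 1
    state.n_rep[r2, word] += 1
    state.n_total += 2
    state.t += 1
    return InteractionEvent(t=state.t, adult=j, target=r1, distractor=r2, word=word)


# ---------------------------------------------------------------------------
# Forgetting
# ---------------------------------------------------------------------------

def apply_naive_forgetting(state: ChildState) -> None:
    """Remove one token from every non-zero slot (in place).

    The caller is responsible for invoking this only when
    ``state.t % m == 0`` (and ``t > 0``); :func:`apply_forgetting` does
    that bookkeeping.
    """
    nonzero = state.c > 0
    state.c -= nonzero
    state.n -= nonzero.sum(axis=1)


def ebbinghaus_rate(n_rw, n, d0_inv: float, d1: float):
    """Per-token deletion probability ``(1/d0) * exp(-(N_rw/N)/d1)``.

    ``N = 0`` (nothing heard yet) is treated as relative repetition 0, so
    the rate equals the initial rate ``1/d0``.  The result is clamped to
    [0, 1] since it is used as a per-timestep probability.  Accepts
    scalars or arrays (broadcast elementwise).
    """
    n_rw = np.asarray(n_rw, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_rw > n_arr):
        raise ValueError("N_rw cannot exceed the total repetition count N")
    rel = np.divide(n_rw, n_arr, out=np.zeros(np.broadcast(n_rw, n_arr).shape),
                    where=n_arr > 0)
    rate = np.clip(d0_inv * np.exp(-rel / d1), 0.0, 1.0)
    return float(rate) if rate.ndim == 0 else rate


def apply_ebbinghaus_forgetting(
    state: ChildState,
    policy: EbbinghausForgetting,
    rng: np.random.Generator,
) -> None:
    """One timestep of stochastic per-token decay (in place).

    Every slot's deletion rate is evaluated on the state's current
    repetition counters (one snapshot for all slots, so the update is
    order-independent), then each of its ``c(r, w)`` tokens is deleted
    independently with that probability.
    """
    if state.n_total == 0 or not np.any(state.c):
        return
    d = ebbinghaus_rate(state.n_rep, state.n_total, policy.d0_inv, policy.d1)
    k = rng.binomial(state.c, d)
    state.c -= k
    state.n -= k.sum(axis=1)


def apply_forgetting(
    state: ChildState,
    policy: ForgettingPolicy,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Apply one iteration's worth of the given forgetting policy.

    Call once per iteration, after :func:`interaction_step`.  For the
    naive policy this fires only on iterations that are multiples of
    ``m``; the Ebbinghaus policy fires every iteration and needs ``rng``.
    """
    if isinstance(policy, NoForgetting):
        return
    if isinstance(policy, NaiveForgetting):
        if state.t > 0 and state.t % policy.m == 0:
            apply_naive_forgetting(state)
        return
    if isinstance(policy, EbbinghausForgetting):
        if rng is None:
            raise ValueError("Ebbinghaus forgetting needs a random generator")
        apply_ebbinghaus_forgetting(state, policy, rng)
        return
    raise TypeError(f"unknown forgetting policy: {policy!r}")
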