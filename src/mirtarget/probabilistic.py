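"""Over-representation probability of the seed motif in a 3'-UTR.

The UTR sequence is modelled as an order-1 Markov chain (UTRs are too
short to parameterise higher orders).  Two tail probabilities of the
number of motif occurrences are provided:

* a binomial approximation ``P(X >= n)`` with per-start probability
  ``initial(m1) * prod transitions``, and
* the exact law of the overlapping occurrence count, obtained by
  embedding the motif's failure-function (KMP) automaton in the
  Markov chain and propagating a joint (state, count) distribution.

Small tail probabilities mark motifs that occur more often than the
background composition explains; reports also carry ``-log10`` of the
tail so that larger values mean more over-represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Utr

__all__ = [
    "MarkovBackground",
    "CountDistribution",
    "fit_markov",
    "motif_start_prob",
    "p_over_binomial",
    "exact_count_distribution",
    "p_over_exact",
]

_BASES = "ACGU"
_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class MarkovBackground:
    """Order-1 nucleotide background model.

    ``initial`` is the stationary/marginal start distribution and
    ``transitions`` the 4x4 row-stochastic matrix, both over A,C,G,U.
    """

    initial: np.ndarray
    transitions: np.ndarray
    pseudocount: float = 1.0
    order: int = 1

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.initial.shape != (4,) or self.transitions.shape != (4, 4):
            raise ValueError("background must be a 4-vector and a 4x4 matrix")
        if np.any(self.initial < 0) or np.any(self.transitions < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.max(np.abs(self.transitions.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition rows must sum to 1")

    @classmethod
    def uniform(cls) -> "MarkovBackground":
        return cls(np.full(4, 0.25), np.full((4, 4), 0.25))


@dataclass
class CountDistribution:
    """Exact pmf of the overlapping occurrence count of ``motif``."""

    length: int
    motif: str
    pmf: np.ndarray

    def tail(self, n_obs: int) -> float:
        if n_obs <= 0:
            return 1.0
        if n_obs >= len(self.pmf):
            return 0.0
        return float(self.pmf[n_obs:].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": np.arange(len(self.pmf)), "probability": self.pmf}
        )


def _codes(seq: str) -> np.ndarray:
    return np.array([_INDEX[c] for c in seq if c in _INDEX], dtype=np.int64)


def fit_markov(utr: Utr | str, pseudocount: float = 1.0) -> MarkovBackground:
    """Estimate the order-1 background from the UTR that it will score.

    Transition rows are smoothed with ``pseudocount``; with
    ``pseudocount=0`` a context never observed falls back to a uniform
    row (with a warning).  Positions with N are dropped.
    """
    seq = utr.seq if isinstance(utr, Utr) else utr
    codes = _codes(seq)
    if len(codes) < 2:
        raise ValueError("need at least 2 unambiguous bases to fit a background")
    counts = np.zeros((4, 4))
    np.add.at(counts, (codes[:-1], codes[1:]), 1.0)
    smoothed = counts + pseudocount
    row_sums = smoothed.sum(axis=1)
    transitions = np.empty((4, 4))
    for i in range(4):
        if row_sums[i] == 0:
            warnings.warn(
                f"no observed transitions from {_BASES[i]}; using a uniform row"
            )
            transitions[i] = 0.25
        else:
            transitions[i] = smoothed[i] / row_sums[i]
    mono = np.bincount(codes, minlength=4).astype(float) + pseudocount
    if mono.sum() == 0:
        initial = np.full(4, 0.25)
    else:
        initial = mono / mono.sum()
    return MarkovBackground(initial, transitions, pseudocount)


def _motif_codes(motif: str) -> np.ndarray:
    if any(c not in _INDEX for c in motif):
        raise ValueError(f"motif {motif!r} contains non-ACGU characters")
    if not motif:
        raise ValueError("motif must be non-empty")
    return np.array([_INDEX[c] for c in motif], dtype=np.int64)


def motif_start_prob(bg: MarkovBackground, motif: str) -> float:
    """Probability that the motif starts at a given position."""
    m = _motif_codes(motif)
    p = bg.initial[m[0]]
    for a, b in zip(m[:-1], m[1:]):
        p *= bg.transitions[a, b]
    return float(p)


def p_over_binomial(
    bg: MarkovBackground, motif: str, length: int, n_obs: int
) -> float:
    """Binomial-approximation tail ``P(X >= n_obs)``.

    ``X ~ Binomial(length - |motif| + 1, motif_start_prob)``; start
    positions are treated as independent trials.
    """
    if n_obs <= 0:
        return 1.0
    trials = length - len(motif) + 1
    if trials <= 0:
        return 0.0
    p = motif_start_prob(bg, motif)
    return float(stats.binom.sf(n_obs - 1, trials, p))


def _kmp_automaton(m: np.ndarray) -> np.ndarray:
    """delta[state, char] over states 0..len(m); state len(m) = just matched.

    After a match the automaton continues from the longest proper
    border, so overlapping occurrences keep counting.
    """
    mlen = len(m)
    fail = np.zeros(mlen + 1, dtype=np.int64)
    k = 0
    for i in range(1, mlen):
        while k > 0 and m[i] != m[k]:
            k = fail[k]
        if m[i] == m[k]:
            k += 1
        fail[i + 1] = k
    delta = np.zeros((mlen + 1, 4), dtype=np.int64)
    for a in range(4):
        delta[0, a] = 1 if m[0] == a else 0
    for s in range(1, mlen + 1):
        for a in range(4):
            if s < mlen and m[s] == a:
                delta[s, a] = s + 1
            else:
                delta[s, a] = delta[fail[s], a]
    return delta


def exact_count_distribution(
    bg: MarkovBackground, motif: str, length: int
) -> CountDistribution:
    """Exact distribution of the overlapping occurrence count.

    The chain state is (automaton state, last emitted base); counts
    are incremented whenever the automaton reaches the accepting
    state.  Complexity O(length * states * support).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    m = _motif_codes(motif)
    mlen = len(m)
    support = max(length - mlen + 1, 0)
    if support == 0:
        return CountDistribution(length, motif, np.array([1.0]))
    delta = _kmp_automaton(m)
    # states: 0..3 = automaton state 0 with last base a; 4 + (s-1) for s >= 1
    n_states = 4 + mlen

    def state_index(s: int, last: int) -> int:
        return last if s == 0 else 4 + s - 1

    def last_base(idx: int) -> int:
        return idx if idx < 4 else int(m[idx - 4])

    P = np.zeros((n_states, support + 1))
    for a in range(4):
        s = int(delta[0, a])
        idx = state_index(s, a)
        hit = 1 if s == mlen else 0
        P[idx, hit] += bg.initial[a]
    for _step in range(length - 1):
        new = np.zeros_like(P)
        for idx in range(n_states):
            row = P[idx]
            if not row.any():
                continue
            prev = last_base(idx)
            s = 0 if idx < 4 else idx - 4 + 1
            for a in range(4):
                p = bg.transitions[prev, a]
                if p == 0.0:
                    continue
                s2 = int(delta[s, a])
                idx2 = state_index(s2, a)
                if s2 == mlen:
                    new[idx2, 1:] += p * row[:-1]
                else:
                    new[idx2] += p * row
        P = new
    pmf = P.sum(axis=0)
    total = pmf.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"pmf sums to {total}")
    return CountDistribution(length, motif, pmf)


def p_over_exact(
    bg: MarkovBackground, motif: str, length: int, n_obs: int
) -> float:
    """Exact tail ``P(X >= n_obs)`` of the occurrence count."""
    if n_obs <= 0:
        return 1.0
    if length < len(motif):
        return 0.0
    return exact_count_distribution(bg, motif, length).tail(n_obs)
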