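"""Synthetic data generators.

Everything the library consumes can be generated here under a single
integer seed: 3'-UTRs from an order-1 Markov background with planted
seed matches, gap-free alignments evolved on a species tree with
region-specific branch scaling (to emulate selected sites), and
feature/response tables with planted linear structure.

The generators are first-class, deterministic (one global seed,
deterministically split per generator) and are what the test-suite
and the end-to-end fixtures are built from.  They intentionally omit
indels, context-dependent substitution and UTR annotation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .conservation import SubstModel, UtrAlignment
from .core import Utr
from .probabilistic import MarkovBackground

__all__ = [
    "SimConfig",
    "child_rng",
    "sim_utr",
    "sim_alignment",
    "sim_feature_table",
]

_BASES = "ACGU"


@dataclass
class SimConfig:
    """Parameters of a full synthetic dataset (see :mod:`mirtarget.cli`)."""

    seed: int
    utr_length: int = 600
    n_utrs: int = 10
    motif: str = "ACAUUCC"
    sites_per_utr: int = 1
    background: MarkovBackground = field(
        default_factory=MarkovBackground.uniform
    )
    tree_newick: str | None = None
    site_rho: float = 0.3
    subst_model: SubstModel = field(default_factory=SubstModel.hky85)


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-generator stream derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def _sample_chain(bg: MarkovBackground, length: int, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.choice(4, p=bg.initial)
    cum = bg.transitions.cumsum(axis=1)
    u = rng.random(length - 1) if length > 1 else np.empty(0)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i - 1], side="right")
    return np.minimum(out, 3)


def sim_utr(
    length: int,
    motif: str,
    n_sites: int,
    background: MarkovBackground | None = None,
    rng: np.random.Generator | None = None,
    utr_id: str = "sim_utr",
    max_tries: int = 1000,
) -> tuple[Utr, list[int]]:
    """Background UTR with ``n_sites`` planted non-overlapping motifs.

    Returns the UTR and the planted start positions (ground truth);
    the background chain may contribute additional matches.
    """
    if len(motif) > length:
        raise ValueError("motif longer than UTR")
    bg = background or MarkovBackground.uniform()
    rng = rng if rng is not None else np.random.default_rng(0)
    seq = _sample_chain(bg, length, rng)
    m = len(motif)
    positions: list[int] = []
    tries = 0
    while len(positions) < n_sites:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_sites} non-overlapping sites of length "
                f"{m} in a UTR of length {length}"
            )
        cand = int(rng.integers(0, length - m + 1))
        if all(abs(cand - p) >= m for p in positions):
            positions.append(cand)
    chars = list("".join(_BASES[b] for b in seq))
    for p in positions:
        chars[p : p + m] = motif
    return Utr(utr_id, "".join(chars)), sorted(positions)


def sim_alignment(
    tree: dendropy.Tree,
    root_seq: str,
    model: SubstModel | None = None,
    region_rho: dict[tuple[int, int], float] | None = None,
    rng: np.random.Generator | None = None,
    ref: str | None = None,
) -> UtrAlignment:
    """Evolve ``root_seq`` down the tree, column-independently, no indels.

    ``region_rho`` maps half-open column ranges to a branch-length
    scaling factor (rho < 1 emulates negative selection; default 1
    everywhere).  The reference row defaults to the first leaf.
    """
    model = model or SubstModel.hky85()
    rng = rng if rng is not None else np.random.default_rng(0)
    ncols = len(root_seq)
    rho = np.ones(ncols)
    for (lo, hi), r in (region_rho or {}).items():
        if not (0 <= lo < hi <= ncols):
            raise ValueError(f"region ({lo}, {hi}) outside sequence")
        if r < 0:
            raise ValueError("rho must be >= 0")
        rho[lo:hi] = r
    codes = np.array([_BASES.index(c) if c in _BASES else 0 for c in root_seq])
    unique_rho = np.unique(rho)
    states: dict[int, np.ndarray] = {}
    rows: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            states[id(nd)] = codes.copy()
        else:
            t = nd.edge.length or 0.0
            parent = states[id(nd.parent_node)]
            child = parent.copy()
            for r in unique_rho:
                sel = rho == r
                if t * r <= 0:
                    continue
                p = model.transition_probs(np.array([t * r]))[0]
                cum = p.cumsum(axis=1)
                u = rng.random(int(sel.sum()))
                child[sel] = (u[:, None] > cum[parent[sel]]).sum(axis=1)
            states[id(nd)] = np.minimum(child, 3)
        if nd.is_leaf():
            rows[nd.taxon.label] = "".join(_BASES[b] for b in states[id(nd)])
    ref = ref or next(iter(rows))
    return UtrAlignment(ref, rows)


def sim_feature_table(
    n: int,
    coefficients: dict[str, float],
    noise_sd: float = 1.0,
    covariance: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    response_name: str = "response",
) -> pd.DataFrame:
    """Features from a given covariance plus a linear Gaussian response.

    Returns a table with one column per feature and a ``response``
    column equal to ``X beta + noise``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    names = list(coefficients)
    p = len(names)
    cov = np.eye(p) if covariance is None else np.asarray(covariance, dtype=float)
    if cov.shape != (p, p):
        raise ValueError("covariance shape does not match coefficient count")
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive semi-definite") from exc
    x = rng.standard_normal((n, p)) @ chol.T
    beta = np.array([coefficients[k] for k in names])
    y = x @ beta + noise_sd * rng.standard_normal(n)
    table = pd.DataFrame(x, columns=names)
    table[response_name] = y
    return table
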