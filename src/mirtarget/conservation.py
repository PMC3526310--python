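"""Evolutionary conservation features of miRNA target sites.

A site that is kept by selection across species is more likely to be
functional.  Three measures are provided, all computed on per-UTR
alignments with a user-supplied species topology:

* **BLS** (branch length score): total branch length of the species
  subtree that retains the target site, on a tree whose branch
  lengths were fitted by maximum likelihood to the full 3'-UTR
  alignment.  Larger = older/broader conservation.
* **negative-selection test** (the ``phylop`` feature): a
  likelihood-ratio test comparing the site columns scored on the
  UTR-fitted tree against the same tree with all branches scaled by a
  factor rho in (0, 1].  Significantly shorter branches at the site
  (rho < 1) indicate negative selection; reported as -log10 P with a
  one-sided 1/2 chi2_0 + 1/2 chi2_1 boundary null.
* **PhastCons averaging**: the mean of per-base conservation scores
  over the seed match, when a score track is available.

Branch lengths are fitted with Felsenstein's pruning algorithm under
JC69 or HKY85; gaps and Ns are treated as missing data.  Tree
manipulation uses DendroPy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats

__all__ = [
    "UtrAlignment",
    "SubstModel",
    "SelectionTestResult",
    "TreeLikelihood",
    "species_with_site",
    "position_conservation_fraction",
    "prune_tree",
    "total_branch_length",
    "fit_branch_lengths",
    "bls",
    "selection_test",
    "phastcons_mean",
]

_BASES = "ACGU"
_INDEX = {b: i for i, b in enumerate(_BASES)}
GAP_CHARS = set("-.")


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class UtrAlignment:
    """A gapped multiple alignment of one 3'-UTR across species.

    ``rows`` maps species name to its gapped sequence (RNA, '-' for
    gaps); all rows have the same column count and ``ref`` names the
    reference species whose gap-stripped row is the UTR itself.
    """

    ref: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if self.ref not in self.rows:
            raise ValueError(f"reference species {self.ref!r} missing from alignment")
        norm = {}
        lengths = set()
        for sp, seq in self.rows.items():
            seq = seq.upper().replace("T", "U")
            bad = set(seq) - set("ACGUN") - GAP_CHARS
            if bad:
                raise ValueError(f"row {sp!r} contains illegal characters {bad}")
            norm[sp] = seq
            lengths.add(len(seq))
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal column counts {sorted(lengths)}")
        self.rows = norm

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def gapless(self, sp: str) -> str:
        return "".join(c for c in self.rows[sp] if c not in GAP_CHARS)

    def ref_to_col(self) -> np.ndarray:
        """Column index of each ungapped reference position."""
        return np.array(
            [i for i, c in enumerate(self.rows[self.ref]) if c not in GAP_CHARS],
            dtype=np.int64,
        )

    def ref_site_columns(self, start: int, end: int) -> np.ndarray:
        mapping = self.ref_to_col()
        if not (0 <= start < end <= len(mapping)):
            raise ValueError(
                f"site [{start}, {end}) outside reference sequence of "
                f"length {len(mapping)}"
            )
        return mapping[start:end]

    def slice_columns(self, cols: np.ndarray) -> "UtrAlignment":
        rows = {sp: "".join(seq[c] for c in cols) for sp, seq in self.rows.items()}
        return UtrAlignment(self.ref, rows)

    def slice_ref_range(self, start: int, end: int) -> "UtrAlignment":
        return self.slice_columns(self.ref_site_columns(start, end))

    def codes(self, species: list[str]) -> np.ndarray:
        """Integer matrix [n_species, n_columns]; -1 = gap/ambiguous."""
        out = np.full((len(species), self.n_columns), -1, dtype=np.int64)
        for r, sp in enumerate(species):
            out[r] = [_INDEX.get(c, -1) for c in self.rows[sp]]
        return out


def species_with_site(
    aln: UtrAlignment,
    motif: str,
    ref_site_range: tuple[int, int],
    mode: str = "anywhere",
) -> tuple[set[str], dict[str, list[int]]]:
    """Species whose row retains the seed match.

    ``mode="anywhere"`` accepts the motif anywhere in the gap-stripped
    row; ``mode="same_columns"`` requires the exact alignment columns
    of the reference site to spell the motif without gaps.  Returns
    the species set and, per species, the (ungapped) match positions.
    """
    if mode not in ("anywhere", "same_columns"):
        raise ValueError(f"unknown mode {mode!r}")
    start, end = ref_site_range
    found: set[str] = set()
    positions: dict[str, list[int]] = {}
    if mode == "anywhere":
        for sp in aln.rows:
            seq = aln.gapless(sp)
            hits = []
            p = seq.find(motif)
            while p != -1:
                hits.append(p)
                p = seq.find(motif, p + 1)
            if hits:
                found.add(sp)
                positions[sp] = hits
        return found, positions
    cols = aln.ref_site_columns(start, end)
    for sp, seq in aln.rows.items():
        chars = "".join(seq[c] for c in cols)
        if chars == motif:
            found.add(sp)
            first = cols[0]
            ungapped = sum(
                1 for c in seq[:first] if c not in GAP_CHARS
            )
            positions[sp] = [ungapped]
    return found, positions


def position_conservation_fraction(
    aln: UtrAlignment, motif: str, ref_site_range: tuple[int, int]
) -> float | None:
    """Fraction of motif-bearing species with the site at the same columns.

    Species without any seed match anywhere are discarded; the
    reference itself is excluded.  ``None`` when no other species
    carries the motif.
    """
    anywhere, _ = species_with_site(aln, motif, ref_site_range, "anywhere")
    same, _ = species_with_site(aln, motif, ref_site_range, "same_columns")
    candidates = anywhere - {aln.ref}
    if not candidates:
        return None
    return len(candidates & same) / len(candidates)


# ---------------------------------------------------------------------------
# Trees


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a DendroPy tree."""
    return dendropy.Tree.get(data=newick, schema="newick")


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of branch lengths; 0 for a single-leaf tree."""
    if len(tree.leaf_nodes()) <= 1:
        return 0.0
    return float(tree.length())


def prune_tree(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``; unifurcations merged, lengths summed."""
    if not keep:
        raise ValueError("keep set is empty")
    labels = leaf_labels(tree)
    missing = set(keep) - labels
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    sub = tree.extract_tree_with_taxa_labels(set(keep))
    # drop any stem above the MRCA of the kept leaves: the induced
    # subtree spans only paths between kept leaves
    while (
        sub.seed_node is not None
        and len(sub.seed_node.child_nodes()) == 1
        and not sub.seed_node.is_leaf()
    ):
        child = sub.seed_node.child_nodes()[0]
        child.parent_node = None
        child.edge.length = None
        sub.seed_node = child
    if sub.seed_node is not None:
        sub.seed_node.edge.length = None
    return sub


def bls(site_species: set[str], fitted_tree: dendropy.Tree) -> float:
    """Branch length score: total length of the retaining subtree."""
    keep = set(site_species) & leaf_labels(fitted_tree)
    if len(keep) <= 1:
        return 0.0
    return total_branch_length(prune_tree(fitted_tree, keep))


# ---------------------------------------------------------------------------
# Substitution models and likelihood


@dataclass
class SubstModel:
    """JC69 or HKY85 substitution model, scaled to 1 sub/site/unit."""

    name: str = "HKY85"
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa: float = 2.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.name not in ("JC69", "HKY85"):
            raise ValueError(f"unknown model {self.name!r}")
        if self.name == "JC69":
            self.freqs = np.full(4, 0.25)
            self.kappa = 1.0
        if abs(self.freqs.sum() - 1.0) > 1e-9 or np.any(self.freqs <= 0):
            raise ValueError("frequencies must be positive and sum to 1")
        self._decompose()

    @classmethod
    def jc69(cls) -> "SubstModel":
        return cls(name="JC69")

    @classmethod
    def hky85(cls, freqs=None, kappa: float = 2.0) -> "SubstModel":
        return cls(
            name="HKY85",
            freqs=np.full(4, 0.25) if freqs is None else freqs,
            kappa=kappa,
        )

    def _decompose(self) -> None:
        pi = self.freqs
        q = np.empty((4, 4))
        # transitions: A<->G (0,2) and C<->U (1,3)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = self.kappa if (i + j) % 2 == 0 else 1.0
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(pi, np.diag(q))
        q /= scale
        d = np.sqrt(pi)
        sym = (q * d[:, None]) / d[None, :]
        w, u = np.linalg.eigh((sym + sym.T) / 2.0)
        self._eigvals = w
        self._left = u / d[:, None]   # D^{-1/2} U
        self._right = (u * d[:, None]).T  # U^T D^{1/2}
        self.rate_matrix = q

    def transition_probs(self, t: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths; shape [len(t), 4, 4]."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        expw = np.exp(self._eigvals[None, :] * t[:, None])
        p = np.einsum("ik,nk,kj->nij", self._left, expw, self._right)
        return np.clip(p, 0.0, None)


class TreeLikelihood:
    """Felsenstein pruning likelihood of alignment columns on a tree.

    The tree is compiled once; ``loglik`` evaluates any assignment of
    branch lengths (in the tree's edge order).  Gaps/Ns contribute a
    partial likelihood of ones (missing data).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        model: SubstModel,
        aln: UtrAlignment,
    ):
        self.tree = tree
        self.model = model
        nodes = list(tree.postorder_node_iter())
        self.nodes = nodes
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.edge_nodes = [nd for nd in nodes if nd.parent_node is not None]
        self.edge_index = {id(nd): e for e, nd in enumerate(self.edge_nodes)}
        self.children = [
            [index[id(ch)] for ch in nd.child_nodes()] for nd in nodes
        ]
        species = [
            nd.taxon.label if nd.is_leaf() else None for nd in nodes
        ]
        present = [sp for sp in species if sp is not None and sp in aln.rows]
        codes = aln.codes(present)
        # compress identical columns
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.weights = counts.astype(float)
        npat = patterns.shape[1]
        self.leaf_partials = []
        row_of = {sp: i for i, sp in enumerate(present)}
        for sp in species:
            if sp is None:
                self.leaf_partials.append(None)
                continue
            part = np.ones((npat, 4))
            if sp in row_of:
                col = patterns[row_of[sp]]
                known = col >= 0
                part[known] = 0.0
                part[known, col[known]] = 1.0
            self.leaf_partials.append(part)

    @property
    def n_edges(self) -> int:
        return len(self.edge_nodes)

    def current_lengths(self) -> np.ndarray:
        return np.array(
            [nd.edge.length if nd.edge.length else 0.0 for nd in self.edge_nodes]
        )

    def set_lengths(self, lengths: np.ndarray) -> None:
        for nd, ln in zip(self.edge_nodes, lengths):
            nd.edge.length = float(ln)

    def loglik(self, lengths: np.ndarray) -> float:
        pmats = self.model.transition_probs(np.asarray(lengths, dtype=float))
        partials: list[np.ndarray | None] = [None] * len(self.nodes)
        npat = len(self.weights)
        scale_acc = np.zeros(npat)
        for i, nd in enumerate(self.nodes):
            if nd.is_leaf():
                partials[i] = self.leaf_partials[i]
                continue
            part = np.ones((npat, 4))
            for ci in self.children[i]:
                child = self.nodes[ci]
                p = pmats[self.edge_index[id(child)]]
                part = part * (partials[ci] @ p.T)
            mx = part.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            part /= mx[:, None]
            scale_acc += np.log(mx)
            partials[i] = part
        root = partials[-1]
        site_l = root @ self.model.freqs
        site_l = np.where(site_l > 0, site_l, 1e-300)
        return float(np.dot(self.weights, np.log(site_l) + scale_acc))


def _deroot(tree: dendropy.Tree) -> dendropy.Tree:
    """Collapse a basal bifurcation so every edge is identifiable."""
    root = tree.seed_node
    if len(root.child_nodes()) == 2 and len(tree.leaf_nodes()) > 2:
        tree.collapse_basal_bifurcation()
    return tree


def fit_branch_lengths(
    aln: UtrAlignment,
    topology: dendropy.Tree,
    model: SubstModel | None = None,
    min_branch: float = 1e-8,
    max_branch: float = 10.0,
    min_columns: int = 20,
) -> dendropy.Tree:
    """ML branch lengths for a fixed topology on a UTR alignment.

    The topology is pruned to the species present in the alignment
    and derooted; branch lengths are optimised by bounded quasi-Newton
    maximisation of the pruning likelihood.  Deterministic for fixed
    inputs.
    """
    model = model or SubstModel.hky85()
    species = set(aln.rows) & leaf_labels(topology)
    if len(species) < 2:
        raise ValueError("need at least 2 species shared by alignment and tree")
    informative = sum(
        1
        for c in range(aln.n_columns)
        if any(aln.rows[sp][c] not in GAP_CHARS for sp in aln.rows)
    )
    if informative < min_columns:
        raise ValueError(
            f"alignment has {informative} non-gap columns; need >= {min_columns}"
        )
    tree = _deroot(prune_tree(topology, species))
    lik = TreeLikelihood(tree, model, aln)
    x0 = np.full(lik.n_edges, 0.1)

    result = optimize.minimize(
        lambda x: -lik.loglik(x),
        x0,
        method="L-BFGS-B",
        bounds=[(min_branch, max_branch)] * lik.n_edges,
    )
    lik.set_lengths(result.x)
    if np.all(result.x <= min_branch * 10):
        warnings.warn(
            "alignment carries no substitutions; all branch lengths at the "
            "lower bound"
        )
    return tree


# ---------------------------------------------------------------------------
# Negative-selection likelihood-ratio test


@dataclass
class SelectionTestResult:
    """Branch-scaling LRT outcome; ``neg_log10_p`` is the feature value."""

    lnl_null: float
    lnl_alt: float
    rho_hat: float
    statistic: float
    p_value: float
    neg_log10_p: float


def selection_test(
    site_aln: UtrAlignment,
    utr_tree: dendropy.Tree,
    model: SubstModel | None = None,
    rho_min: float = 1e-4,
    min_site_columns: int = 6,
) -> SelectionTestResult:
    """Test whether branch lengths shrink at the site (negative selection).

    The null scores the site columns on the UTR-fitted tree; the
    alternative rescales every branch by rho in (0, 1].  The statistic
    2(lnL_alt - lnL_null) is referred to the boundary mixture
    1/2 chi2_0 + 1/2 chi2_1.
    """
    model = model or SubstModel.hky85()
    if site_aln.n_columns < min_site_columns:
        raise ValueError(
            f"site alignment has {site_aln.n_columns} columns; "
            f"need >= {min_site_columns}"
        )
    informative = [
        sp
        for sp in site_aln.rows
        if any(c not in GAP_CHARS for c in site_aln.rows[sp])
    ]
    if len(set(informative) & leaf_labels(utr_tree)) < 2:
        return SelectionTestResult(0.0, 0.0, 1.0, 0.0, 1.0, 0.0)
    tree = utr_tree.clone(depth=1)
    lik = TreeLikelihood(tree, model, site_aln)
    base = lik.current_lengths()

    def neg(rho: float) -> float:
        return -lik.loglik(base * rho)

    lnl_null = -neg(1.0)
    opt = optimize.minimize_scalar(
        neg, bounds=(rho_min, 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(1.0, lnl_null), (float(opt.x), -float(opt.fun)), (rho_min, -neg(rho_min))]
    rho_hat, lnl_alt = max(candidates, key=lambda c: c[1])
    statistic = max(0.0, 2.0 * (lnl_alt - lnl_null))
    if statistic <= 1e-10:
        p_value = 1.0
    else:
        p_value = 0.5 * float(stats.chi2.sf(statistic, df=1))
    p_value = min(max(p_value, 1e-300), 1.0)
    return SelectionTestResult(
        lnl_null=lnl_null,
        lnl_alt=lnl_alt,
        rho_hat=rho_hat,
        statistic=statistic,
        p_value=p_value,
        neg_log10_p=float(-np.log10(p_value)),
    )


# ---------------------------------------------------------------------------
# Per-base conservation scores


def phastcons_mean(
    scores: np.ndarray,
    site_range: tuple[int, int],
) -> tuple[float | None, float]:
    """Mean per-base conservation score over the site.

    ``scores`` is an array over UTR positions with NaN marking bases
    the track does not cover.  Returns (mean over covered bases,
    covered fraction); the mean is ``None`` when nothing is covered.
    """
    start, end = site_range
    scores = np.asarray(scores, dtype=float)
    if not (0 <= start < end <= len(scores)):
        raise ValueError("site outside score track")
    window = scores[start:end]
    covered = ~np.isnan(window)
    coverage = covered.mean()
    if not covered.any():
        return None, 0.0
    return float(window[covered].mean()), float(coverage)
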