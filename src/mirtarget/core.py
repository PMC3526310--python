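"""Sequence data model, seed definition and seed-match scanning.

A miRNA represses an mRNA mostly through Watson-Crick pairing of its
"seed" region (positions 2-7 or 2-8 from the miRNA 5' end) with the
3'-UTR of the transcript.  This module holds the basic value types
(:class:`MiRNA`, :class:`Utr`, :class:`SeedSpec`, :class:`TargetSite`),
the scanner that locates seed matches, and the orchestration entry
point :func:`evaluate_site` that dispatches per-site feature
computations to the specialised modules.

Coordinates are 0-based half-open everywhere in the library; reports
convert to 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "SequenceError",
    "MiRNA",
    "Utr",
    "SeedSpec",
    "TargetSite",
    "FeatureContext",
    "KNOWN_FEATURES",
    "normalize_sequence",
    "reverse_complement",
    "seed_match_motif",
    "find_seed_matches",
    "evaluate_site",
]

RNA_ALPHABET = frozenset("ACGUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: Watson-Crick pairs (and, separately, the two wobble pairs).
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})


class SequenceError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,U,N}."""


def normalize_sequence(raw: str) -> str:
    """Return ``raw`` uppercased with T converted to U.

    Characters outside the RNA alphabet (N allowed) raise
    :class:`SequenceError` naming the 1-based offending position.
    """
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise SequenceError(f"illegal character {ch!r} at position {pos}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an RNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence, 5'->3', alphabet {A,C,G,U}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_sequence(self.seq))
        if "N" in self.seq:
            raise SequenceError(f"miRNA {self.id!r} contains ambiguous bases")
        if len(self.seq) < 15:
            raise ValueError(
                f"miRNA {self.id!r} has length {len(self.seq)} < 15"
            )


@dataclass(frozen=True)
class Utr:
    """A 3'-UTR sequence, 5'->3'.  Ambiguous bases (N) are permitted."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_sequence(self.seq))

    @property
    def has_ambiguous(self) -> bool:
        return "N" in self.seq

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SeedSpec:
    """Definition of the seed region on the miRNA.

    ``seed_start`` is 1-based on the miRNA (default 2, the canonical
    seed start); ``seed_length`` is 6, 7 or 8; ``allow_gu`` turns on
    G:U wobble matching in the scanner only.
    """

    seed_start: int = 2
    seed_length: int = 7
    allow_gu: bool = False

    def __post_init__(self) -> None:
        if self.seed_start < 1:
            raise ValueError("seed_start is 1-based and must be >= 1")
        if self.seed_length not in (6, 7, 8):
            raise ValueError("seed_length must be one of 6, 7, 8")

    def validate_for(self, mirna: MiRNA) -> None:
        if self.seed_start + self.seed_length - 1 > len(mirna.seq):
            raise ValueError(
                f"seed region [{self.seed_start}, "
                f"{self.seed_start + self.seed_length - 1}] exceeds miRNA "
                f"{mirna.id!r} of length {len(mirna.seq)}"
            )


@dataclass
class TargetSite:
    """One seed-matched miRNA/UTR interaction.

    ``site_start``/``site_end`` are 0-based half-open UTR coordinates of
    the seed match; ``features`` maps feature name -> value (``None``
    marks a feature whose resources were unavailable).
    """

    utr_id: str
    mirna_id: str
    site_start: int
    site_end: int
    features: dict[str, float | None] = field(default_factory=dict)

    @property
    def seed_length(self) -> int:
        return self.site_end - self.site_start


def seed_match_motif(mirna: MiRNA, spec: SeedSpec) -> str:
    """The seed-match motif: reverse complement of the seed region.

    Returned 5'->3' as it appears in the UTR.
    """
    spec.validate_for(mirna)
    lo = spec.seed_start - 1
    seed = mirna.seq[lo : lo + spec.seed_length]
    return reverse_complement(seed)


def _pairs(utr_char: str, mirna_char: str, allow_gu: bool) -> bool:
    if (utr_char, mirna_char) in WC_PAIRS:
        return True
    return allow_gu and (utr_char, mirna_char) in GU_PAIRS


def find_seed_matches(mirna: MiRNA, utr: Utr, spec: SeedSpec) -> list[TargetSite]:
    """All seed matches of ``mirna`` in ``utr`` (overlaps allowed).

    With ``allow_gu=False`` this is an exact scan for the reverse
    complement of the seed; positions containing N never match.  With
    ``allow_gu=True`` each UTR base must form a Watson-Crick or G:U
    pair with the corresponding seed base.  Sites are sorted by start.
    """
    spec.validate_for(mirna)
    m = spec.seed_length
    sites: list[TargetSite] = []
    if not spec.allow_gu:
        motif = seed_match_motif(mirna, spec)
        start = utr.seq.find(motif)
        while start != -1:
            sites.append(TargetSite(utr.id, mirna.id, start, start + m))
            start = utr.seq.find(motif, start + 1)
        return sites
    lo = spec.seed_start - 1
    seed = mirna.seq[lo : lo + m]
    for start in range(len(utr.seq) - m + 1):
        window = utr.seq[start : start + m]
        # UTR window is antiparallel to the seed: window[k] pairs
        # seed[m - 1 - k].
        if all(_pairs(window[k], seed[m - 1 - k], True) for k in range(m)):
            sites.append(TargetSite(utr.id, mirna.id, start, start + m))
    return sites


# ---------------------------------------------------------------------------
# Feature orchestration


KNOWN_FEATURES = (
    "dg_duplex",
    "dg_binding",
    "dg_open",
    "dg_total",
    "p_over_binomial",
    "p_over_exact",
    "bls",
    "phylop",
    "au_content",
    "utr_position",
    "pairing3",
    "phastcons",
)


@dataclass
class FeatureContext:
    """All loaded resources needed to evaluate features.

    Only the resources required by the requested features have to be
    present; a missing resource yields ``None`` for the feature plus a
    warning, never a silent zero.
    """

    mirnas: dict[str, MiRNA]
    utrs: dict[str, Utr]
    seed_spec: SeedSpec = field(default_factory=SeedSpec)
    #: thermodynamic backend (thermo.NearestNeighborBackend compatible)
    backend: object | None = None
    constraint_window: int = 70
    fold_flank: int = 70
    #: per-UTR multiple alignments, utr_id -> conservation.UtrAlignment
    alignments: dict[str, object] = field(default_factory=dict)
    #: species topology (dendropy.Tree) used for branch-length fitting
    species_tree: object | None = None
    #: substitution model for conservation features
    subst_model: object | None = None
    #: how a species "contains" the site: "anywhere" or "same_columns"
    site_mode: str = "anywhere"
    #: per-UTR conservation score arrays (NaN = missing base)
    score_tracks: dict[str, object] = field(default_factory=dict)

    _markov_cache: dict = field(default_factory=dict, repr=False)
    _count_cache: dict = field(default_factory=dict, repr=False)
    _tree_cache: dict = field(default_factory=dict, repr=False)

    def default_backend(self):
        if self.backend is None:
            from . import thermo

            self.backend = thermo.NearestNeighborBackend()
        return self.backend

    def markov_for(self, utr: Utr):
        from . import probabilistic

        if utr.id not in self._markov_cache:
            self._markov_cache[utr.id] = probabilistic.fit_markov(utr)
        return self._markov_cache[utr.id]

    def site_count(self, mirna: MiRNA, utr: Utr) -> int:
        key = (mirna.id, utr.id)
        if key not in self._count_cache:
            self._count_cache[key] = len(
                find_seed_matches(mirna, utr, self.seed_spec)
            )
        return self._count_cache[key]

    def fitted_tree_for(self, utr_id: str):
        """Branch lengths fitted to the full-UTR alignment (cached)."""
        from . import conservation

        if utr_id not in self._tree_cache:
            aln = self.alignments[utr_id]
            model = self.subst_model or conservation.SubstModel.hky85()
            self._tree_cache[utr_id] = conservation.fit_branch_lengths(
                aln, self.species_tree, model
            )
        return self._tree_cache[utr_id]


def _missing(name: str, resource: str) -> None:
    warnings.warn(
        f"feature {name!r} skipped: required resource ({resource}) not loaded",
        stacklevel=3,
    )


def evaluate_site(
    site: TargetSite,
    context: FeatureContext,
    feature_names: list[str],
) -> TargetSite:
    """Return a copy of ``site`` with the requested features filled in.

    Unknown feature names raise :class:`ValueError`; features whose
    resources are missing are set to ``None`` with a warning.
    """
    unknown = [f for f in feature_names if f not in KNOWN_FEATURES]
    if unknown:
        raise ValueError(
            f"unknown feature(s) {unknown}; valid names: {list(KNOWN_FEATURES)}"
        )
    site = replace(site, features=dict(site.features))
    if not feature_names:
        return site

    from . import conservation, probabilistic, seqfeatures, thermo

    mirna = context.mirnas[site.mirna_id]
    utr = context.utrs[site.utr_id]
    feats = site.features

    wants = set(feature_names)
    thermo_wanted = wants & {"dg_duplex", "dg_binding", "dg_open", "dg_total"}
    if thermo_wanted:
        backend = context.default_backend()
        region = thermo.site_region(utr.seq, site, len(mirna.seq))
        if {"dg_duplex", "dg_total"} & wants:
            feats["dg_duplex"] = thermo.dg_duplex(
                mirna.seq, region, backend
            ).free_energy
        if "dg_binding" in wants:
            feats["dg_binding"] = thermo.dg_binding(mirna.seq, region, backend)
        if {"dg_open", "dg_total"} & wants:
            feats["dg_open"] = thermo.dg_open(
                utr,
                site.site_start,
                site.site_end,
                backend,
                constraint_window=context.constraint_window,
                fold_flank=context.fold_flank,
            )
        if "dg_total" in wants:
            feats["dg_total"] = thermo.dg_total(
                feats["dg_duplex"], feats["dg_open"]
            )
        # drop helper values computed only for dg_total
        for name in ("dg_duplex", "dg_open"):
            if name in feats and name not in wants:
                del feats[name]

    if wants & {"p_over_binomial", "p_over_exact"}:
        bg = context.markov_for(utr)
        motif = seed_match_motif(mirna, context.seed_spec)
        n_obs = context.site_count(mirna, utr)
        if "p_over_binomial" in wants:
            feats["p_over_binomial"] = probabilistic.p_over_binomial(
                bg, motif, len(utr.seq), n_obs
            )
        if "p_over_exact" in wants:
            feats["p_over_exact"] = probabilistic.p_over_exact(
                bg, motif, len(utr.seq), n_obs
            )

    cons_wanted = wants & {"bls", "phylop"}
    if cons_wanted:
        aln = context.alignments.get(site.utr_id)
        if aln is None or context.species_tree is None:
            for name in cons_wanted:
                _missing(name, "alignment and species tree")
                feats[name] = None
        else:
            fitted = context.fitted_tree_for(site.utr_id)
            motif = seed_match_motif(mirna, context.seed_spec)
            if "bls" in wants:
                species, _ = conservation.species_with_site(
                    aln, motif, (site.site_start, site.site_end),
                    mode=context.site_mode,
                )
                feats["bls"] = conservation.bls(species, fitted)
            if "phylop" in wants:
                model = context.subst_model or conservation.SubstModel.hky85()
                result = conservation.selection_test(
                    aln.slice_ref_range(site.site_start, site.site_end),
                    fitted,
                    model,
                )
                feats["phylop"] = result.neg_log10_p

    if "phastcons" in wants:
        track = context.score_tracks.get(site.utr_id)
        if track is None:
            _missing("phastcons", "conservation score track")
            feats["phastcons"] = None
        else:
            mean, _cov = conservation.phastcons_mean(
                track, (site.site_start, site.site_end)
            )
            feats["phastcons"] = mean

    if "au_content" in wants:
        feats["au_content"] = seqfeatures.au_content(utr, site)
    if "pairing3" in wants:
        feats["pairing3"] = seqfeatures.pairing3(mirna, utr, site)
    if "utr_position" in wants:
        feats["utr_position"] = seqfeatures.utr_position(len(utr.seq), site)

    return site
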