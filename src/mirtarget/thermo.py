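"""Thermodynamic target-site features.

Four free-energy features describe the energetics of RISC engagement:

``dg_duplex``
    minimum free energy of the joint miRNA:site secondary structure
    (intra- and intermolecular pairs),
``dg_binding``
    ensemble free energy of association: G(pair ensemble) minus the
    monomer ensemble energies,
``dg_open``
    cost of forcing the target region single-stranded (accessibility):
    G(window, site constrained open) - G(window, unconstrained) >= 0,
``dg_total``
    ``dg_duplex + dg_open``, the net system energy.

Folding goes through a pluggable backend.  The shipped
:class:`NearestNeighborBackend` implements a reduced nearest-neighbour
model (stacking terms plus affine loop costs; see
:mod:`mirtarget._fold`) so that every energy can be verified against a
brute-force Boltzmann sum.  Absolute energies differ from full
Turner-parameter implementations; the rankings are the product.  An
adapter satisfying :class:`BackendContract` can drop in an external
folding library.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from ._fold import (
    EnergyModel,
    FoldEngine,
    encode,
    enumerate_pairings,
    structure_energy,
)
from .core import TargetSite, Utr

__all__ = [
    "EnergyModel",
    "FoldResult",
    "BackendContract",
    "NearestNeighborBackend",
    "site_region",
    "dg_duplex",
    "dg_binding",
    "dg_open",
    "dg_total",
    "enumerate_structures",
    "dot_bracket",
]


@dataclass
class FoldResult:
    """Free energy (kcal/mol) plus, for MFE folds, the paired indices."""

    free_energy: float
    structure: list[tuple[int, int]] = field(default_factory=list)
    kind: str = "mfe"
    #: total length of the folded sequence(s); cut position for duplexes
    length: int = 0
    cut: int | None = None


class BackendContract(ABC):
    """Operations a folding backend must provide."""

    @abstractmethod
    def duplex_mfe(self, a: str, b: str) -> FoldResult: ...

    @abstractmethod
    def duplex_ensemble(self, a: str, b: str) -> FoldResult: ...

    @abstractmethod
    def fold_ensemble(
        self, seq: str, constraint_mask: np.ndarray | None = None
    ) -> FoldResult: ...


class NearestNeighborBackend(BackendContract):
    """In-repo reference backend over the reduced nearest-neighbour model."""

    def __init__(self, model: EnergyModel | None = None):
        self.engine = FoldEngine(model)

    @property
    def model(self) -> EnergyModel:
        return self.engine.model

    def duplex_mfe(self, a: str, b: str) -> FoldResult:
        _check_lengths(a, b)
        energy, pairs, n = self.engine.duplex_mfe(encode(a), encode(b))
        return FoldResult(energy, pairs, kind="mfe", length=n, cut=len(a))

    def duplex_ensemble(self, a: str, b: str) -> FoldResult:
        _check_lengths(a, b)
        z = self.engine.duplex_partition(encode(a), encode(b))
        g = -self.model.rt * math.log(z)
        return FoldResult(g, [], kind="ensemble", length=len(a) + len(b), cut=len(a))

    def fold_ensemble(
        self, seq: str, constraint_mask: np.ndarray | None = None
    ) -> FoldResult:
        g = self.engine.ensemble_free_energy(encode(seq), constraint_mask)
        return FoldResult(g, [], kind="ensemble", length=len(seq))


def _check_lengths(a: str, b: str) -> None:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("duplex sequences must be at least 2 nt long")


def site_region(utr_seq: str, site: TargetSite, mirna_len: int) -> str:
    """UTR region folded against the miRNA.

    The seed match extended upstream (5') so that the region length
    equals the miRNA length, truncated at the UTR start.
    """
    start = max(0, site.site_end - mirna_len)
    return utr_seq[start : site.site_end]


def dg_duplex(mirna_seq: str, region: str, backend: BackendContract) -> FoldResult:
    """MFE of the miRNA:site duplex (<= 0; 0 if nothing pairs)."""
    return backend.duplex_mfe(mirna_seq, region)


def dg_binding(mirna_seq: str, region: str, backend: BackendContract) -> float:
    """Ensemble binding free energy: G(pair) - G(miRNA) - G(site)."""
    g_pair = backend.duplex_ensemble(mirna_seq, region).free_energy
    g_a = backend.fold_ensemble(mirna_seq).free_energy
    g_b = backend.fold_ensemble(region).free_energy
    return g_pair - g_a - g_b


def dg_open(
    utr: Utr | str,
    site_start: int,
    site_end: int,
    backend: BackendContract,
    constraint_window: int = 70,
    fold_flank: int = 70,
) -> float:
    """Opening free energy of the target site (accessibility, >= 0).

    The single-strand constraint covers ``constraint_window``
    nucleotides centred on the site; the folded window extends the
    constrained segment by ``fold_flank`` on each side.  Both are
    truncated at the UTR ends.
    """
    seq = utr.seq if isinstance(utr, Utr) else utr
    n = len(seq)
    if not (0 <= site_start < site_end <= n):
        raise ValueError(
            f"site [{site_start}, {site_end}) outside UTR of length {n}"
        )
    centre2 = site_start + site_end  # 2 * centre
    half = constraint_window / 2.0
    c_lo = max(0, int(math.ceil(centre2 / 2.0 - half)))
    c_hi = min(n, c_lo + constraint_window)
    c_lo = max(0, min(c_lo, c_hi - 1))
    w_lo = max(0, c_lo - fold_flank)
    w_hi = min(n, c_hi + fold_flank)
    window = seq[w_lo:w_hi]
    mask = np.zeros(len(window), dtype=bool)
    mask[c_lo - w_lo : c_hi - w_lo] = True
    g_closed = backend.fold_ensemble(window).free_energy
    g_open = backend.fold_ensemble(window, mask).free_energy
    dg = g_open - g_closed
    if dg < 0.0:
        if dg < -1e-6:
            raise AssertionError(f"negative opening energy {dg}")
        dg = 0.0
    return dg


def dg_total(dg_duplex_value: float, dg_open_value: float) -> float:
    """Net system energy: duplex gain plus opening cost."""
    if dg_duplex_value is None or dg_open_value is None:
        raise ValueError("dg_total requires dg_duplex and dg_open")
    return dg_duplex_value + dg_open_value


def enumerate_structures(
    seq: str,
    model: EnergyModel | None = None,
    second: str | None = None,
    constraint_mask: np.ndarray | None = None,
    max_len: int = 14,
) -> list[tuple[tuple[tuple[int, int], ...], float]]:
    """Brute-force oracle: every structure with its energy.

    For a pair of molecules the duplex initiation cost is included in
    structures with intermolecular pairs.  Total length is capped at
    ``max_len``.
    """
    model = model if model is not None else EnergyModel.default()
    if second is None:
        codes, cut = encode(seq), None
    else:
        codes, cut = encode(seq + second), len(seq)
    out = []
    for pairs in enumerate_pairings(codes, cut, constraint_mask, max_len=max_len):
        e = structure_energy(codes, pairs, model, cut)
        if math.isfinite(e):
            out.append((pairs, e))
    return out


def dot_bracket(length: int, pairs, cut: int | None = None) -> str:
    """Dot-bracket rendering; an ``&`` marks the cut of a duplex."""
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    if cut is not None:
        chars.insert(cut, "&")
    return "".join(chars)
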