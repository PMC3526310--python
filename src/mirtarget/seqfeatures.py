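"""TargetScan-style context-score sequence features.

Three features of the local sequence context of a seed match:

* ``au_content`` — A/U fraction of the flanking sequence, weighted by
  1/d where d is the distance from the site boundary (closer bases
  matter more; AU-rich flanks are less structured, hence more
  accessible),
* ``pairing3`` — supplementary Watson-Crick pairing of the miRNA 3'
  region (positions >= 9; the 13-16 core scores double) with the UTR
  upstream of the seed match,
* ``utr_position`` — distance to the nearest 3'-UTR end, capped so
  that very long UTRs do not dominate linear models.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import MiRNA, TargetSite, Utr, WC_PAIRS

__all__ = ["AuWeightScheme", "au_content", "pairing3", "utr_position"]


@dataclass(frozen=True)
class AuWeightScheme:
    """Flank size and 1/d weights used by :func:`au_content`."""

    flank: int = 30

    def weight(self, d: int) -> float:
        if not 1 <= d <= self.flank:
            raise ValueError(f"distance {d} outside 1..{self.flank}")
        return 1.0 / d


def au_content(
    utr: Utr | str,
    site: TargetSite,
    scheme: AuWeightScheme | None = None,
) -> float | None:
    """Weighted A/U fraction of the two site flanks, in [0, 1].

    Bases at distance d from the site boundary get weight 1/d; N bases
    are excluded from numerator and denominator.  Returns ``None``
    when no usable flank base exists.
    """
    scheme = scheme or AuWeightScheme()
    seq = utr.seq if isinstance(utr, Utr) else utr
    num = den = 0.0
    for d in range(1, scheme.flank + 1):
        w = scheme.weight(d)
        for pos in (site.site_start - d, site.site_end - 1 + d):
            if 0 <= pos < len(seq) and seq[pos] != "N":
                den += w
                if seq[pos] in "AU":
                    num += w
    if den == 0.0:
        return None
    return num / den


def pairing3(
    mirna: MiRNA,
    utr: Utr | str,
    site: TargetSite,
    max_offset: int = 8,
) -> float:
    """3'-compensatory pairing score (>= 0).

    For each alignment offset, the best contiguous run of Watson-Crick
    pairs between miRNA positions >= 9 and the UTR upstream of the
    seed match is scored (1.0 per pair at miRNA 13-16, 0.5 elsewhere)
    and penalised by ``0.5 * max(0, |offset| - 2)``; the maximum over
    offsets is returned, floored at 0.
    """
    seq = utr.seq if isinstance(utr, Utr) else utr
    m3 = mirna.seq[8:]  # miRNA positions 9.. (1-based)
    best = 0.0
    for offset in range(-max_offset, max_offset + 1):
        run = 0.0
        best_run = 0.0
        for k, mchar in enumerate(m3):
            p = 9 + k  # 1-based miRNA position
            upos = site.site_start - 1 - k - offset
            if 0 <= upos < len(seq) and (seq[upos], mchar) in WC_PAIRS:
                run += 1.0 if 13 <= p <= 16 else 0.5
                best_run = max(best_run, run)
            else:
                run = 0.0
        score = best_run - 0.5 * max(0, abs(offset) - 2)
        best = max(best, score)
    return max(best, 0.0)


def utr_position(utr_len: int, site: TargetSite, cap: int | None = 1500) -> float:
    """Distance (nt) from the site to the nearest UTR end."""
    if not (0 <= site.site_start < site.site_end <= utr_len):
        raise ValueError("site outside UTR")
    d = min(site.site_start, utr_len - site.site_end)
    if cap is not None:
        d = min(d, cap)
    return float(d)
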