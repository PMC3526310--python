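"""Readers and writers for the formats the library consumes.

FASTA (miRNAs, UTRs) goes through Biopython's ``SeqIO``; MAF blocks
through ``AlignIO``; Newick trees through DendroPy.  Per-base
conservation tracks are read from fixed-step / variable-step wiggle
and bedGraph text.  Conventions:

* FASTA record ids are the miRNA/transcript ids; descriptions are
  ignored; duplicate ids are an error.
* MAF 's' line sources are ``species.utr_id``; the first row of each
  block is the reference species, and the block is keyed by the
  reference row's utr_id.
* wiggle/bedGraph ``chrom`` equals the utr_id; positions are mapped
  onto UTR coordinates via a declared ``offset`` (track position -
  offset = 0-based UTR position; wiggle positions themselves are
  1-based per the format).
"""

from __future__ import annotations

import os
from typing import Iterable

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import UtrAlignment
from .core import MiRNA, Utr, normalize_sequence

__all__ = [
    "read_mirna_fasta",
    "read_utr_fasta",
    "write_fasta",
    "read_maf",
    "write_maf",
    "read_newick",
    "write_newick",
    "read_wiggle",
    "track_to_array",
]


class FormatError(ValueError):
    """Malformed input file."""


def _read_fasta_records(path: str) -> list[tuple[str, str]]:
    records = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_mirna_fasta(path: str) -> dict[str, MiRNA]:
    return {rid: MiRNA(rid, seq) for rid, seq in _read_fasta_records(path)}


def read_utr_fasta(path: str) -> dict[str, Utr]:
    return {rid: Utr(rid, seq) for rid, seq in _read_fasta_records(path)}


def write_fasta(records: Iterable[MiRNA | Utr], path: str) -> None:
    seq_records = [
        SeqRecord(Seq(rec.seq), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(seq_records, path, "fasta")


def read_maf(path: str) -> dict[str, UtrAlignment]:
    """Per-UTR alignments keyed by the reference row's utr_id."""
    out: dict[str, UtrAlignment] = {}
    for block in AlignIO.parse(path, "maf"):
        rows: dict[str, str] = {}
        ref_species = None
        utr_id = None
        for rec in block:
            if "." not in rec.id:
                raise FormatError(
                    f"{path}: MAF source {rec.id!r} is not 'species.utr_id'"
                )
            species, _, suffix = rec.id.partition(".")
            if species in rows:
                raise FormatError(
                    f"{path}: duplicate species {species!r} in block"
                )
            if ref_species is None:
                ref_species, utr_id = species, suffix
            rows[species] = str(rec.seq)
        if utr_id in out:
            raise FormatError(f"{path}: duplicate block for UTR {utr_id!r}")
        out[utr_id] = UtrAlignment(ref_species, rows)
    if not out:
        raise FormatError(f"{path}: no MAF blocks found")
    return out


def write_maf(alignments: dict[str, UtrAlignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for utr_id, aln in alignments.items():
            fh.write("a score=0.0\n")
            order = [aln.ref] + [sp for sp in aln.rows if sp != aln.ref]
            for sp in order:
                seq = aln.rows[sp]
                ungapped = sum(1 for c in seq if c not in "-.")
                fh.write(
                    f"s {sp}.{utr_id} 0 {ungapped} + {ungapped} {seq}\n"
                )
            fh.write("\n")


def read_newick(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick")


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True)


def read_wiggle(path: str) -> dict[str, list[tuple[int, float]]]:
    """Parse fixed-step/variable-step wiggle or bedGraph text.

    Returns, per chrom (= utr_id), a list of (1-based position, value).
    """
    tracks: dict[str, list[tuple[int, float]]] = {}
    mode = None
    chrom = None
    start = step = span = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if fields[0] in ("fixedStep", "variableStep"):
                mode = fields[0]
                params = dict(f.split("=", 1) for f in fields[1:])
                if "chrom" not in params:
                    raise FormatError(f"{path}:{lineno}: missing chrom")
                chrom = params["chrom"]
                span = int(params.get("span", 1))
                step = int(params.get("step", 1))
                start = int(params.get("start", 1))
                tracks.setdefault(chrom, [])
                continue
            if len(fields) == 4:  # bedGraph: chrom start end value
                c, lo, hi, value = fields
                tracks.setdefault(c, [])
                for pos in range(int(lo) + 1, int(hi) + 1):  # bedGraph is 0-based
                    tracks[c].append((pos, float(value)))
                continue
            if mode == "fixedStep":
                if len(fields) != 1:
                    raise FormatError(f"{path}:{lineno}: bad fixedStep value line")
                for s in range(span):
                    tracks[chrom].append((start + s, float(fields[0])))
                start += step
            elif mode == "variableStep":
                if len(fields) != 2:
                    raise FormatError(f"{path}:{lineno}: bad variableStep line")
                pos = int(fields[0])
                for s in range(span):
                    tracks[chrom].append((pos + s, float(fields[1])))
            else:
                raise FormatError(f"{path}:{lineno}: data before any header")
    if not tracks:
        raise FormatError(f"{path}: no track data found")
    return tracks


def track_to_array(
    entries: list[tuple[int, float]],
    utr_len: int,
    offset: int = 0,
) -> np.ndarray:
    """Per-base score array over the UTR (NaN where uncovered).

    A track entry at 1-based position ``pos`` maps to UTR index
    ``pos - 1 - offset``.
    """
    arr = np.full(utr_len, np.nan)
    for pos, value in entries:
        idx = pos - 1 - offset
        if 0 <= idx < utr_len:
            arr[idx] = value
    return arr
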