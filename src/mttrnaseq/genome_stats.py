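"""Whole-genome summary statistics for deposited organelle records.

Length, GC content, the longest exact substring present at a minimum number
of genomic locations (master-circle repeat detection), and intact tRNA gene
counts from feature annotations.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .reference_db import GenomeAnnotation, load_annotations

__all__ = [
    "read_genome_record",
    "sequence_length",
    "gc_percent",
    "longest_multicopy_repeat",
    "count_intact_trna_genes",
]


def read_genome_record(path: str | Path):
    """First record of a GenBank or FASTA file (format sniffed)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    fmt = "genbank" if first.startswith("LOCUS") else "fasta"
    return next(SeqIO.parse(str(path), fmt))


def sequence_length(seq: str) -> int:
    return len(seq)


def gc_percent(seq: str, ndigits: int | None = 1) -> float:
    """100 * (G + C) / length, optionally rounded."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
    return round(gc, ndigits) if ndigits is not None else gc


_MOD = (1 << 61) - 1
_BASE = 131


def _has_repeat(seq: str, length: int, min_copies: int) -> bool:
    """True iff some exact substring of ``length`` occurs at >= min_copies
    distinct start positions (Rabin-Karp grouping + literal verification)."""
    n = len(seq)
    if length > n or length < 1:
        return False
    h = 0
    # after h = h*B + b the outgoing character carries coefficient B^length
    power = pow(_BASE, length, _MOD)
    groups: dict[int, list[int]] = {}
    data = seq.encode()
    for i, b in enumerate(data):
        h = (h * _BASE + b) % _MOD
        if i >= length:
            h = (h - data[i - length] * power) % _MOD
        if i >= length - 1:
            groups.setdefault(h, []).append(i - length + 1)
    for positions in groups.values():
        if len(positions) < min_copies:
            continue
        by_string: dict[str, int] = {}
        for p in positions:
            s = seq[p:p + length]
            by_string[s] = by_string.get(s, 0) + 1
            if by_string[s] >= min_copies:
                return True
    return False


def longest_multicopy_repeat(seq: str, min_copies: int = 4, circular: bool = True
                             ) -> int:
    """Length of the longest exact substring occurring at >= min_copies
    distinct genomic locations.

    With ``circular`` the sequence is virtually circularized (occurrences are
    counted at distinct start offsets modulo the genome length). Direct-strand
    occurrences only.
    """
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        return 0

    def check(length: int) -> bool:
        if length > n:
            return False
        if circular:
            # windows then start at 0..n-1: every rotation once, no aliasing
            extended = seq + seq[: length - 1]
        else:
            extended = seq
        return _has_repeat(extended, length, min_copies)

    lo, hi = 0, n + 1  # overlapping occurrences allow lengths up to n
    # exponential probe keeps typical runs fast (true repeat lengths are small
    # relative to the genome)
    probe = 1
    while probe <= hi and check(probe):
        lo = probe
        probe *= 2
    hi = min(hi, probe)
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if check(mid):
            lo = mid
        else:
            hi = mid
    return lo


def count_intact_trna_genes(annotation: GenomeAnnotation | str | Path,
                            distinct_names: bool = False) -> int:
    """Count tRNA features, excluding pseudogene-flagged entries.

    With ``distinct_names`` features sharing a gene name (repeat-region
    copies) are counted once.
    """
    if not isinstance(annotation, GenomeAnnotation):
        annotation = load_annotations(annotation)
    trnas = [f for f in annotation.features if f.type == "tRNA"]
    if distinct_names:
        return len({f.name or f.feature_id for f in trnas})
    return len(trnas)
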