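"""Survey of CCA-tailed reads at non-tRNA mitogenome positions.

Discriminates post-transcriptionally added CCA tails from genome-encoded ones,
merges supporting reads into loci, classifies loci as t-elements vs orphan
stem-loops by distance to the closest annotated feature, and computes the
per-library percentage of CCA-tailed reads mapping outside tRNA genes.

A pairing-maximization fold heuristic (Watson-Crick + GU, minimum hairpin
loop 3) provides advisory structure metadata; it is never used as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mapper import AlignmentHit, GenomeIndex, map_to_genome
from .read_prep import Library, ReadFamily, min_count_filter
from .reference_db import GenomeAnnotation

__all__ = [
    "CCA_STATUSES",
    "StemLoopRecord",
    "FoldResult",
    "detect_cca",
    "closest_feature",
    "classify_loci",
    "cca_percentages",
    "fold_heuristic",
    "survey",
    "DEFAULT_T_ELEMENT_WINDOW",
]

CCA_STATUSES = ("post_transcriptional", "genome_encoded", "absent")
DEFAULT_T_ELEMENT_WINDOW = 150

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class StemLoopRecord:
    locus: tuple[str, int, int, str]  # (seq_id, start, end, strand)
    representative_sequence: str
    locus_class: str  # tRNA_overlap | t_element | orphan_stem_loop
    nearest_feature: tuple[str, int] | None
    read_support: dict[str, int] = field(default_factory=dict)
    cca_status: str = "absent"
    supporting_families: tuple[str, ...] = ()


def detect_cca(sequence: str, hit: AlignmentHit, genome: str) -> str:
    """Classify the read's 3' CCA as genome-encoded, post-transcriptional or absent.

    The read's terminal three bases are projected onto genome coordinates via
    the alignment (strand-aware; the projection assumes the 3'-terminal region
    aligns without gaps, extending past the aligned span where the terminus is
    soft-clipped). The status is genome-encoded only when the corresponding
    genomic context also reads CCA in the read's orientation.
    """
    seq = sequence.upper()
    if not seq.endswith("CCA"):
        return "absent"
    n = len(seq)
    _, qe = hit.query_interval
    rs, re = hit.reference_interval
    bases = []
    for p in (n - 3, n - 2, n - 1):
        if hit.strand == "+":
            g = re + (p - qe)
            base = genome[g].upper() if 0 <= g < len(genome) else "N"
        else:
            g = rs + (qe - p - 1)
            base = _COMP.get(genome[g].upper(), "N") if 0 <= g < len(genome) else "N"
        bases.append(base)
    return "genome_encoded" if "".join(bases) == "CCA" else "post_transcriptional"


def closest_feature(locus: tuple[str, int, int, str], annotation: GenomeAnnotation
                    ) -> tuple[str, int] | None:
    """Closest annotated feature and signed gap distance.

    Overlap gives distance 0. Otherwise the gap in bp is signed negative when
    the feature lies 5' of the locus on the locus strand. Ties are broken by
    the lowest feature start coordinate.
    """
    seq_id, start, end, strand = locus
    feats = annotation.on_seq(seq_id)
    if not feats:
        return None
    best: tuple[int, int, str, int] | None = None  # (gap, f.start, feature_id, signed)
    for f in feats:
        if f.start < end and start < f.end:
            gap, signed = 0, 0
        elif f.end <= start:
            gap = start - f.end
            signed = -gap if strand == "+" else gap
        else:
            gap = f.start - end
            signed = gap if strand == "+" else -gap
        key = (gap, f.start)
        if best is None or key < (best[0], best[1]):
            best = (gap, f.start, f.feature_id, signed)
    return best[2], best[3]


def _merge_intervals(items: list[tuple[str, int, int, str, int]]
                     ) -> list[list[int]]:
    """Single-linkage merge of (seq_id, start, end, strand, idx) on >=1 bp overlap."""
    clusters: list[list[int]] = []
    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for seq_id, start, end, strand, idx in items:
        by_key.setdefault((seq_id, strand), []).append((start, end, idx))
    for _, ivs in sorted(by_key.items()):
        ivs.sort()
        current: list[int] = []
        cur_end = None
        for start, end, idx in ivs:
            if cur_end is None or start >= cur_end:
                if current:
                    clusters.append(current)
                current = [idx]
                cur_end = end
            else:
                current.append(idx)
                cur_end = max(cur_end, end)
        if current:
            clusters.append(current)
    return clusters


def classify_loci(
    hits: Sequence[tuple[ReadFamily, AlignmentHit, str]],
    annotation: GenomeAnnotation,
    t_element_window: int = DEFAULT_T_ELEMENT_WINDOW,
) -> list[StemLoopRecord]:
    """Merge genome hits of CCA-tailed reads into loci and classify them.

    ``hits`` holds (family, genome hit, cca_status) triples; all loci of a
    family may be supplied. Loci overlapping a tRNA feature are classified
    tRNA_overlap; otherwise t_element when within ``t_element_window`` bp of
    the nearest feature, else orphan_stem_loop.
    """
    items = [(h.reference_id, h.reference_interval[0], h.reference_interval[1], h.strand, i)
             for i, (_, h, _) in enumerate(hits)]
    records: list[StemLoopRecord] = []
    for cluster in _merge_intervals(items):
        members = [hits[i] for i in cluster]
        seq_id = members[0][1].reference_id
        strand = members[0][1].strand
        start = min(h.reference_interval[0] for _, h, _ in members)
        end = max(h.reference_interval[1] for _, h, _ in members)
        rep = max(members, key=lambda m: (m[0].total, m[0].sequence))
        support: dict[str, int] = {}
        fams = set()
        for fam, _, _ in members:
            if fam.family_id in fams:
                continue
            fams.add(fam.family_id)
            for lib, c in fam.counts.items():
                support[lib] = support.get(lib, 0) + c
        overlaps_trna = any(
            f.type == "tRNA" and f.start < end and start < f.end
            for f in annotation.on_seq(seq_id)
        )
        nearest = closest_feature((seq_id, start, end, strand), annotation)
        if overlaps_trna:
            locus_class = "tRNA_overlap"
        elif nearest is not None and abs(nearest[1]) <= t_element_window:
            locus_class = "t_element"
        else:
            locus_class = "orphan_stem_loop"
        records.append(
            StemLoopRecord(
                locus=(seq_id, start, end, strand),
                representative_sequence=rep[0].sequence,
                locus_class=locus_class,
                nearest_feature=nearest,
                read_support=support,
                cca_status=rep[2],
                supporting_families=tuple(sorted(fams)),
            )
        )
    records.sort(key=lambda r: r.locus)
    return records


def cca_percentages(
    per_family: Sequence[tuple[ReadFamily, AlignmentHit, str]],
    annotation: GenomeAnnotation,
    libraries: Sequence[Library],
) -> pd.DataFrame:
    """Per-library percentage of CCA-tailed mito-mapping reads at non-tRNA loci.

    ``per_family`` holds one entry per family: its best-scoring genome locus
    and CCA status (per-read accounting: each read counts once even when the
    family has several genome loci). The denominator is all CCA-tailed reads
    with a genome hit; libraries without CCA reads get NA.
    """
    lib_ids = [lib.library_id for lib in libraries]
    total = {lib: 0 for lib in lib_ids}
    non_trna = {lib: 0 for lib in lib_ids}
    for fam, hit, status in per_family:
        if status == "absent" or hit is None:
            continue
        start, end = hit.reference_interval
        overlaps_trna = any(
            f.type == "tRNA" and f.start < end and start < f.end
            for f in annotation.on_seq(hit.reference_id)
        )
        for lib in lib_ids:
            c = fam.counts.get(lib, 0)
            total[lib] += c
            if not overlaps_trna:
                non_trna[lib] += c
    rows = []
    for lib in lib_ids:
        pct = 100.0 * non_trna[lib] / total[lib] if total[lib] else float("nan")
        rows.append({"library_id": lib, "n_cca_reads_total": total[lib],
                     "n_cca_reads_non_tRNA": non_trna[lib], "percentage": pct})
    return pd.DataFrame(rows).set_index("library_id")


def survey(
    families: Iterable[ReadFamily],
    genome: Mapping[str, str] | str,
    annotation: GenomeAnnotation,
    libraries: Sequence[Library],
    min_total: int = 3,
    t_element_window: int = DEFAULT_T_ELEMENT_WINDOW,
    min_identity: float = 90.0,
    min_coverage: float = 90.0,
) -> tuple[list[StemLoopRecord], pd.DataFrame]:
    """Run the full genome-mapping CCA survey on min-count-filtered families."""
    if isinstance(genome, str):
        genome = {"genome": genome}
    index = GenomeIndex(genome)
    kept = min_count_filter(list(families), min_total)
    all_hits: list[tuple[ReadFamily, AlignmentHit, str]] = []
    best_per_family: list[tuple[ReadFamily, AlignmentHit, str]] = []
    for fam in kept:
        hits = map_to_genome(fam, genome, min_identity=min_identity,
                             min_coverage=min_coverage, index=index)
        if not hits:
            continue
        best = max(hits, key=lambda h: h.score)
        status = detect_cca(fam.sequence, best, genome[best.reference_id])
        best_per_family.append((fam, best, status))
        if status != "absent":
            for h in hits:
                all_hits.append((fam, h, detect_cca(fam.sequence, h,
                                                    genome[h.reference_id])))
    records = classify_loci(all_hits, annotation, t_element_window)
    report = cca_percentages(best_per_family, annotation, libraries)
    return records, report


# ---------------------------------------------------------------------------
# fold heuristic

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_HAIRPIN_LOOP = 3


@dataclass
class FoldResult:
    max_pairs: int
    pairs: list[int]  # partner index per position, -1 if unpaired
    cloverleaf_flag: bool


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def fold_heuristic(sequence: str) -> FoldResult:
    """Base-pair-maximization fold (Nussinov-style) with a cloverleaf test.

    Watson-Crick and GU pairs, minimum hairpin loop of 3. The cloverleaf flag
    is true when the traced structure contains >=3 hairpin stems of >=3 bp
    enclosed by a closing stem of >=4 bp. The flag is advisory metadata only.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n > 120:
        raise ValueError(f"fold_heuristic supports sequences up to 120 nt, got {n}")
    if n == 0:
        return FoldResult(0, [], False)
    loop = MIN_HAIRPIN_LOOP
    N = [[0] * n for _ in range(n)]
    for span in range(loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]
            if N[i][j - 1] > best:
                best = N[i][j - 1]
            if _can_pair(seq[i], seq[j]) and N[i + 1][j - 1] + 1 > best:
                best = N[i + 1][j - 1] + 1
            row_i = N[i]
            for k in range(i + 1, j):
                v = row_i[k] + N[k + 1][j]
                if v > best:
                    best = v
            N[i][j] = best

    pairs = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < loop + 1:
            continue
        if N[i][j] == N[i + 1][j]:
            stack.append((i + 1, j))
        elif N[i][j] == N[i][j - 1]:
            stack.append((i, j - 1))
        else:
            # prefer a bifurcation into independent sub-structures before
            # closing the (i, j) pair: keeps multiloop arms as local hairpins
            split = -1
            for k in range(i + 1, j):
                if N[i][k] > 0 and N[k + 1][j] > 0 and N[i][k] + N[k + 1][j] == N[i][j]:
                    split = k
                    break
            if split >= 0:
                stack.append((i, split))
                stack.append((split + 1, j))
            else:
                pairs[i] = j
                pairs[j] = i
                stack.append((i + 1, j - 1))

    return FoldResult(N[0][n - 1], pairs, _has_cloverleaf(pairs))


def _helices(pairs: Sequence[int]) -> list[tuple[int, int, int]]:
    """Maximal stacked helices as (outer_i, outer_j, stack_length)."""
    out = []
    n = len(pairs)
    seen = set()
    for i in range(n):
        j = pairs[i]
        if j <= i or i in seen:
            continue
        # start of a helix iff the enclosing (i-1, j+1) pair does not stack on it
        if i > 0 and pairs[i - 1] == j + 1:
            continue
        length = 1
        a, b = i, j
        while a + 1 < n and b - 1 >= 0 and pairs[a + 1] == b - 1 and b - 1 > a + 1:
            a += 1
            b -= 1
            length += 1
        for x in range(i, a + 1):
            seen.add(x)
        out.append((i, j, length))
    return out


def _has_cloverleaf(pairs: Sequence[int], closing_min: int = 4,
                    arm_min: int = 3, n_arms: int = 3) -> bool:
    helices = _helices(pairs)
    if not helices:
        return False

    def innermost(h):
        i, j, length = h
        return i + length - 1, j - length + 1

    hairpins = []
    for h in helices:
        a, b = innermost(h)
        if not any(a < x < b and pairs[x] > x for x in range(a + 1, b)):
            if h[2] >= arm_min:
                hairpins.append(h)
    for h in helices:
        if h[2] < closing_min:
            continue
        a, b = innermost(h)
        inside = [hp for hp in hairpins if a < hp[0] and hp[1] < b]
        if len(inside) >= n_arms:
            return True
    return False
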