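"""Reference universe: tRNA gene records, collapsed reference sets, genome
annotations and the mitogenome anticodon inventory.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) and
GenBank records are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "TRNAGeneRecord",
    "ReferenceEntry",
    "ReferenceSet",
    "Feature",
    "GenomeAnnotation",
    "AnticodonInventory",
    "CrossOriginIdentityWarning",
    "ValidationError",
    "AnnotationParseError",
    "load_annotations",
    "write_gff3",
    "build_reference_set",
    "anticodon_inventory",
    "load_trna_table",
    "write_reference_fasta",
    "load_reference_set",
]

ORIGINS = ("mitochondrial", "nuclear", "plastid", "contaminant")
FEATURE_TYPES = ("tRNA", "rRNA", "protein_coding", "pseudogene", "other")

#: decoding classes for the CAU anticodon; all other anticodons are "standard"
DECODING_CLASSES = ("standard", "elongator-Met", "initiator/fMet", "Ile-lysidine")

_DNA = set("ACGT")


class ValidationError(ValueError):
    """Raised when a record violates a documented invariant."""


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed."""


class CrossOriginIdentityWarning(UserWarning):
    """Two genes from different origins share an identical mature sequence."""


def normalize_anticodon(anticodon: str) -> str:
    """Uppercase and present as RNA (T -> U)."""
    ac = anticodon.strip().upper().replace("T", "U")
    if len(ac) != 3 or any(b not in "ACGU" for b in ac):
        raise ValidationError(f"anticodon must be a 3-letter ACGU/ACGT triplet, got {anticodon!r}")
    return ac


def decoding_class_for(amino_acid: str, anticodon: str) -> str:
    """Assign the decoding class, disambiguating CAU by amino-acid metadata.

    CAU is carried by elongator Met, the organellar initiator (fMet), the
    cytosolic initiator (iMet) and lysidine-modified Ile; the class is taken
    from metadata, never inferred from sequence.
    """
    ac = normalize_anticodon(anticodon)
    if ac != "CAU":
        return "standard"
    aa = amino_acid.strip()
    if aa in ("fMet", "iMet"):
        return "initiator/fMet"
    if aa == "Met":
        return "elongator-Met"
    if aa == "Ile":
        return "Ile-lysidine"
    raise ValidationError(
        f"CAU anticodon requires amino_acid in {{Met, fMet, iMet, Ile}}, got {amino_acid!r}"
    )


@dataclass(frozen=True)
class TRNAGeneRecord:
    """One tRNA gene: origin, identity metadata and mature (intron-free) sequence."""

    gene_id: str
    origin: str
    amino_acid: str
    anticodon: str
    sequence: str
    is_pseudogene: bool = False
    source_locus: tuple | None = None  # (seq_id, start, end, strand)

    def __post_init__(self):
        if self.origin not in ORIGINS:
            raise ValidationError(f"{self.gene_id}: origin {self.origin!r} not in {ORIGINS}")
        seq = self.sequence.upper()
        if not seq or set(seq) - _DNA:
            raise ValidationError(
                f"{self.gene_id}: sequence must be non-empty over {{A,C,G,T}}"
            )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "anticodon", normalize_anticodon(self.anticodon))
        # raises on inconsistent CAU metadata
        decoding_class_for(self.amino_acid, self.anticodon)

    @property
    def decoding_class(self) -> str:
        return decoding_class_for(self.amino_acid, self.anticodon)


@dataclass(frozen=True)
class ReferenceEntry:
    reference_id: str
    sequence: str
    contributors: tuple[str, ...]
    origin: str
    amino_acid: str
    anticodon: str


@dataclass
class ReferenceSet:
    """Collapsed mapping references: one entry per distinct (sequence, origin)."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.reference_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("reference_ids must be unique")
        pairs = [(e.sequence, e.origin) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("reference sequences must be distinct within an origin")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self, reference_id: str) -> ReferenceEntry:
        lookup = getattr(self, "_by_id", None)
        if lookup is None or len(lookup) != len(self.entries):
            lookup = {e.reference_id: e for e in self.entries}
            self._by_id = lookup
        return lookup[reference_id]

    def merged(self, other: "ReferenceSet") -> "ReferenceSet":
        return ReferenceSet(entries=list(self.entries) + list(other.entries))


@dataclass(frozen=True)
class Feature:
    feature_id: str
    seq_id: str
    type: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    name: str = ""

    def __post_init__(self):
        if self.type not in FEATURE_TYPES:
            raise ValidationError(f"feature type {self.type!r} not in {FEATURE_TYPES}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.feature_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValidationError(f"feature {self.feature_id}: strand must be + or -")


@dataclass
class GenomeAnnotation:
    """Gene boundaries used by closest-feature classification."""

    features: list[Feature] = field(default_factory=list)
    seq_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for f in self.features:
            n = self.seq_lengths.get(f.seq_id)
            if n is not None and f.end > n:
                raise ValidationError(
                    f"feature {f.feature_id} exceeds length of {f.seq_id} ({f.end} > {n})"
                )

    def __len__(self) -> int:
        return len(self.features)

    def on_seq(self, seq_id: str) -> list[Feature]:
        return [f for f in self.features if f.seq_id == seq_id]


@dataclass
class AnticodonInventory:
    """Set of (amino_acid, anticodon, decoding_class) from intact genes of one genome."""

    entries: frozenset[tuple[str, str, str]] = frozenset()

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, item) -> bool:
        return item in self.entries

    def decoding_classes(self) -> set[str]:
        return {dc for _, _, dc in self.entries}


# ---------------------------------------------------------------------------
# annotation I/O

_GFF_TYPE_MAP = {
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "gene": "protein_coding",
    "CDS": "protein_coding",
    "mRNA": "protein_coding",
    "protein_coding": "protein_coding",
    "pseudogene": "pseudogene",
    "tRNA_pseudogene": "pseudogene",
}

_GENBANK_TYPE_MAP = {
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "CDS": "protein_coding",
    "gene": None,  # skip bare gene wrappers; typed children carry the information
}


def _parse_gff3(path: Path) -> GenomeAnnotation:
    features: list[Feature] = []
    seq_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    seq_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seq_id, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise AnnotationParseError(f"{path}:{lineno}: invalid coordinate range")
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            fid = attr_map.get("ID", f"feature_{lineno}")
            name = attr_map.get("Name", attr_map.get("gene", ""))
            internal_type = _GFF_TYPE_MAP.get(ftype, "other")
            if attr_map.get("pseudo") == "true" or attr_map.get("pseudogene"):
                internal_type = "pseudogene"
            features.append(
                Feature(
                    feature_id=fid,
                    seq_id=seq_id,
                    type=internal_type,
                    start=start_i - 1,  # GFF3 1-based inclusive -> 0-based half-open
                    end=end_i,
                    strand=strand if strand in "+-" else "+",
                    name=name,
                )
            )
    return GenomeAnnotation(features=features, seq_lengths=seq_lengths)


def _parse_genbank(path: Path) -> GenomeAnnotation:
    features: list[Feature] = []
    seq_lengths: dict[str, int] = {}
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises bare ValueError on bad records
        raise AnnotationParseError(f"{path}: failed to parse GenBank record: {exc}") from exc
    if not records:
        raise AnnotationParseError(f"{path}: no GenBank records found")
    counter = 0
    for rec in records:
        seq_lengths[rec.id] = len(rec)
        for feat in rec.features:
            mapped = _GENBANK_TYPE_MAP.get(feat.type, "other")
            if feat.type == "source":
                continue
            if mapped is None:
                continue
            counter += 1
            quals = feat.qualifiers
            name = (quals.get("gene") or quals.get("product") or [""])[0]
            fid = (quals.get("locus_tag") or [f"{rec.id}_f{counter}"])[0]
            ftype = "pseudogene" if "pseudo" in quals or "pseudogene" in quals else mapped
            features.append(
                Feature(
                    feature_id=fid,
                    seq_id=rec.id,
                    type=ftype,
                    start=int(feat.location.start),  # Biopython is already 0-based half-open
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    name=name,
                )
            )
    return GenomeAnnotation(features=features, seq_lengths=seq_lengths)


def load_annotations(path: str | Path) -> GenomeAnnotation:
    """Load a GFF3 or GenBank flatfile into internal 0-based half-open coordinates.

    Format is sniffed from the first non-blank line (``LOCUS`` => GenBank).
    """
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
        else:
            first = ""
    if first.startswith("LOCUS"):
        return _parse_genbank(path)
    return _parse_gff3(path)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write features back out as GFF3 (converting to 1-based inclusive)."""
    inverse = {"tRNA": "tRNA", "rRNA": "rRNA", "protein_coding": "gene",
               "pseudogene": "pseudogene", "other": "region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seq_id, n in sorted(annotation.seq_lengths.items()):
            fh.write(f"##sequence-region {seq_id} 1 {n}\n")
        for f in annotation.features:
            attrs = f"ID={f.feature_id}"
            if f.name:
                attrs += f";Name={f.name}"
            fh.write(
                "\t".join(
                    [f.seq_id, "mttrnaseq", inverse[f.type], str(f.start + 1), str(f.end),
                     ".", f.strand, ".", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# reference construction


def excise_introns(sequence: str, introns: Sequence[tuple[int, int]]) -> str:
    """Remove 0-based half-open intron intervals from a gene sequence."""
    if not introns:
        return sequence
    ivs = sorted(introns)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValidationError(f"overlapping intron intervals [{s1},{e1}) and [{s2},{e2})")
    out, prev = [], 0
    for s, e in ivs:
        if not (0 <= s < e <= len(sequence)):
            raise ValidationError(f"intron [{s},{e}) outside sequence of length {len(sequence)}")
        out.append(sequence[prev:s])
        prev = e
    out.append(sequence[prev:])
    return "".join(out)


def build_reference_set(
    genes: Iterable[TRNAGeneRecord],
    introns: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> ReferenceSet:
    """Collapse identical mature sequences into single references.

    Identical sequences are merged only within an origin; a cross-origin
    identity (e.g. a plastid-derived mitochondrial gene identical to the
    plastid copy) keeps separate entries and raises
    :class:`CrossOriginIdentityWarning`.
    """
    introns = introns or {}
    mature: list[TRNAGeneRecord] = []
    for g in genes:
        iv = introns.get(g.gene_id)
        if iv:
            seq = excise_introns(g.sequence, iv)
            g = TRNAGeneRecord(
                gene_id=g.gene_id, origin=g.origin, amino_acid=g.amino_acid,
                anticodon=g.anticodon, sequence=seq, is_pseudogene=g.is_pseudogene,
                source_locus=g.source_locus,
            )
        mature.append(g)

    groups: dict[tuple[str, str], list[TRNAGeneRecord]] = {}
    for g in mature:
        groups.setdefault((g.sequence, g.origin), []).append(g)

    # cross-origin identity warning
    by_seq: dict[str, set[str]] = {}
    for seq, origin in groups:
        by_seq.setdefault(seq, set()).add(origin)
    for seq, origins in by_seq.items():
        if len(origins) > 1:
            members = [g.gene_id for (s, o), gs in groups.items() if s == seq for g in gs]
            warnings.warn(
                f"identical mature sequence shared across origins {sorted(origins)} "
                f"by genes {sorted(members)}; entries kept separate",
                CrossOriginIdentityWarning,
                stacklevel=2,
            )

    entries = []
    counters: dict[str, int] = {}
    for (seq, origin), members in sorted(groups.items()):
        metas = {(g.amino_acid, g.anticodon) for g in members}
        if len(metas) > 1:
            ids = ", ".join(sorted(g.gene_id for g in members))
            raise ValidationError(
                f"identical sequences with conflicting anticodon metadata: {ids} ({sorted(metas)})"
            )
        aa, ac = next(iter(metas))
        key = f"{origin}_{aa}_{ac}"
        counters[key] = counters.get(key, 0) + 1
        entries.append(
            ReferenceEntry(
                reference_id=f"{key}_{counters[key]}",
                sequence=seq,
                contributors=tuple(sorted(g.gene_id for g in members)),
                origin=origin,
                amino_acid=aa,
                anticodon=ac,
            )
        )
    return ReferenceSet(entries=entries)


def anticodon_inventory(genes: Iterable[TRNAGeneRecord]) -> AnticodonInventory:
    """Anticodon inventory of one genome's intact (non-pseudogene) tRNA genes."""
    genes = list(genes)
    origins = {g.origin for g in genes}
    if len(origins) > 1:
        raise ValidationError(f"inventory requires genes from a single origin, got {sorted(origins)}")
    by_pair: dict[tuple[str, str], str] = {}
    for g in genes:
        if g.is_pseudogene:
            continue
        key = (g.amino_acid, g.anticodon)
        dc = g.decoding_class
        if by_pair.setdefault(key, dc) != dc:
            raise ValidationError(f"conflicting decoding classes for {key}")
    return AnticodonInventory(
        entries=frozenset((aa, ac, dc) for (aa, ac), dc in by_pair.items())
    )


# ---------------------------------------------------------------------------
# tabular / FASTA I/O


def _parse_intron_field(text: str) -> tuple[tuple[int, int], ...]:
    text = text.strip()
    if not text or text == ".":
        return ()
    out = []
    for chunk in text.split(","):
        s, e = chunk.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def load_trna_table(path: str | Path) -> tuple[list[TRNAGeneRecord], dict[str, tuple]]:
    """Read a tab-separated tRNA gene metadata table.

    Columns: gene_id, origin, amino_acid, anticodon, pseudogene (0/1),
    sequence, introns (``start-end[,start-end...]`` 0-based half-open, or ``.``).
    Returns (records, intron intervals by gene_id).
    """
    genes, introns = [], {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        required = {"gene_id", "origin", "amino_acid", "anticodon", "pseudogene", "sequence"}
        missing = required - set(idx)
        if missing:
            raise AnnotationParseError(f"{path}: missing columns {sorted(missing)}")
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            gid = cols[idx["gene_id"]]
            genes.append(
                TRNAGeneRecord(
                    gene_id=gid,
                    origin=cols[idx["origin"]],
                    amino_acid=cols[idx["amino_acid"]],
                    anticodon=cols[idx["anticodon"]],
                    sequence=cols[idx["sequence"]],
                    is_pseudogene=cols[idx["pseudogene"]] in ("1", "true", "True"),
                )
            )
            if "introns" in idx and len(cols) > idx["introns"]:
                iv = _parse_intron_field(cols[idx["introns"]])
                if iv:
                    introns[gid] = iv
    return genes, introns


def write_reference_fasta(refset: ReferenceSet, fasta_path: str | Path,
                          tsv_path: str | Path | None = None) -> None:
    """Write collapsed references as FASTA plus a metadata sidecar TSV."""
    with open(fasta_path, "w") as fh:
        for e in refset:
            fh.write(f">{e.reference_id}\n{e.sequence}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("reference_id\torigin\tamino_acid\tanticodon\tcontributors\n")
            for e in refset:
                fh.write(
                    f"{e.reference_id}\t{e.origin}\t{e.amino_acid}\t{e.anticodon}\t"
                    + ",".join(e.contributors)
                    + "\n"
                )


def load_reference_set(fasta_path: str | Path, tsv_path: str | Path) -> ReferenceSet:
    """Re-read a collapsed reference FASTA + sidecar TSV written by this module."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    entries = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            rid = cols[idx["reference_id"]]
            entries.append(
                ReferenceEntry(
                    reference_id=rid,
                    sequence=seqs[rid],
                    contributors=tuple(cols[idx["contributors"]].split(",")),
                    origin=cols[idx["origin"]],
                    amino_acid=cols[idx["amino_acid"]],
                    anticodon=normalize_anticodon(cols[idx["anticodon"]]),
                )
            )
    return ReferenceSet(entries=entries)
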