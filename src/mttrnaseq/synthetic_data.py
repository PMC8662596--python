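"""Seeded synthetic dual-compartment tRNA-seq experiments with known truth.

Generates a reference universe (mito/nuclear/plastid tRNA-like sequences, a
toy annotated mitogenome containing t-element and orphan stem-loop loci) and
per-library FASTQ reads drawn multinomially from mixture proportions that
encode configured mito-vs-total enrichments. All randomness flows from a
single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .read_prep import Library
from .reference_db import (
    Feature,
    GenomeAnnotation,
    ReferenceSet,
    TRNAGeneRecord,
    build_reference_set,
)

__all__ = [
    "SimulationConfig",
    "ReferenceUniverse",
    "SimulationTruth",
    "simulate_references",
    "simulate_libraries",
    "truth_report",
    "write_fastq",
    "simulate_to_dir",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# amino-acid cycle for invented genes; CAU-anticodon families are only
# produced when explicitly configured (decoding-class logic has its own tests)
_AA_CYCLE = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val", "Met",
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_mito_trnas: int = 6
    n_nuclear_families: int = 20
    members_per_family: int = 2
    n_plastid_refs: int = 3
    n_excluded_families: int | None = None  # default: n_mito_trnas
    import_log2fc: tuple[float, ...] | None = None  # per nuclear family
    mito_trna_log2fc: float = 6.0
    mito_total_fraction: float = 0.01
    plastid_total_fraction: float = 0.05
    plastid_contamination_fraction: float = 0.01
    t_element_read_fraction: float = 0.003
    misincorporation_rate: float = 0.02
    indel_rate: float = 0.0
    reads_per_library: int = 20000
    n_mito_replicates: int = 2
    n_total_replicates: int = 2
    include_identical_pair: bool = False
    genome_length: int = 30000
    species: str = "synthetica"

    def __post_init__(self):
        if not (0.0 <= self.misincorporation_rate <= 0.15):
            raise ValueError("misincorporation_rate must be in [0, 0.15]")
        for name in ("mito_total_fraction", "plastid_total_fraction",
                     "plastid_contamination_fraction", "t_element_read_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_excluded_families is None:
            self.n_excluded_families = min(self.n_mito_trnas, self.n_nuclear_families)
        if self.n_mito_trnas + self.n_nuclear_families + self.n_plastid_refs > 62:
            raise ValueError("requested anticodon count exceeds the available pool")
        if self.import_log2fc is not None:
            self.import_log2fc = tuple(float(x) for x in self.import_log2fc)
            if len(self.import_log2fc) != self.n_nuclear_families:
                raise ValueError("import_log2fc length must equal n_nuclear_families")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def default_import_log2fc(self) -> tuple[float, ...]:
        """Excluded families spaced over [-5, -2], imported over [0.5, 4]."""
        if self.import_log2fc is not None:
            return self.import_log2fc
        n_ex = self.n_excluded_families
        n_im = self.n_nuclear_families - n_ex
        ex = np.linspace(-5.0, -2.0, n_ex) if n_ex else np.array([])
        im = np.linspace(0.5, 4.0, n_im) if n_im else np.array([])
        return tuple(np.concatenate([ex, im]))

    def libraries(self) -> list[Library]:
        libs = []
        for i in range(self.n_mito_replicates):
            libs.append(Library(f"mito_{i + 1}", self.species, "mito_isolate", i + 1))
        for i in range(self.n_total_replicates):
            libs.append(Library(f"total_{i + 1}", self.species, "total_cellular", i + 1))
        return libs


@dataclass
class ReferenceUniverse:
    refset: ReferenceSet
    genes: list[TRNAGeneRecord]
    genome: dict[str, str]
    annotation: GenomeAnnotation
    t_element_loci: list[tuple[str, int, int, str]]
    orphan_locus: tuple[str, int, int, str]
    #: source_id -> transcript sequence actually read out (with CCA tail)
    transcripts: dict[str, str]
    #: source_id -> kind in {mito_trna, nuclear, plastid, t_element, orphan}
    kinds: dict[str, str]
    #: nuclear family key (amino_acid, anticodon) -> member source_ids
    families: dict[tuple[str, str], list[str]]
    #: family key -> True if an intact mito gene shares the anticodon
    family_excluded: dict[tuple[str, str], bool]


@dataclass
class SimulationTruth:
    proportions: dict[str, dict[str, float]]  # library_id -> source_id -> p
    family_log2fc: dict[tuple[str, str], float]
    source_log2fc: dict[str, float]
    t_element_loci: list[tuple[str, int, int, str]]
    provenance: dict[str, list[str]] = dc_field(default_factory=dict)
    read_counts: dict[str, dict[str, int]] = dc_field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _anticodon_pool(rng: np.random.Generator) -> list[str]:
    pool = []
    for a in "ACGU":
        for b in "ACGU":
            for c in "ACGU":
                ac = a + b + c
                if ac in ("CAU", "NNN"):
                    continue
                pool.append(ac)
    rng.shuffle(pool)
    return pool


def _trna_like(rng: np.random.Generator, anticodon: str) -> str:
    """tRNA-like body of 70-90 nt with the anticodon embedded at position 32."""
    length = int(rng.integers(70, 91))
    seq = list(_random_seq(rng, length))
    seq[32:35] = list(anticodon.replace("U", "T"))
    return "".join(seq)


def simulate_references(config: SimulationConfig, rng: np.random.Generator
                        ) -> ReferenceUniverse:
    """Build reference sequences, the toy annotated mitogenome, and metadata."""
    pool = _anticodon_pool(rng)
    mito_acs = [pool.pop() for _ in range(config.n_mito_trnas)]
    genes: list[TRNAGeneRecord] = []
    transcripts: dict[str, str] = {}
    kinds: dict[str, str] = {}

    mito_seqs = []
    for i, ac in enumerate(mito_acs):
        aa = _AA_CYCLE[i % len(_AA_CYCLE)]
        seq = _trna_like(rng, ac)
        gid = f"mt-{aa.lower()}{ac}"
        genes.append(TRNAGeneRecord(gid, "mitochondrial", aa, ac, seq))
        transcripts[gid] = seq + "CCA"
        kinds[gid] = "mito_trna"
        mito_seqs.append((gid, seq))

    families: dict[tuple[str, str], list[str]] = {}
    family_excluded: dict[tuple[str, str], bool] = {}
    for f in range(config.n_nuclear_families):
        if f < config.n_excluded_families:
            ac = mito_acs[f % len(mito_acs)]
            aa = _AA_CYCLE[f % len(mito_acs) % len(_AA_CYCLE)]
            excluded = True
        else:
            ac = pool.pop()
            aa = _AA_CYCLE[f % len(_AA_CYCLE)]
            excluded = False
        key = (aa, ac)
        members = []
        base = _trna_like(rng, ac)
        for m in range(config.members_per_family):
            seq = list(base)
            # members must sit further apart than the identity threshold
            # tolerates (>10% divergence), else their reads cross-map and the
            # unique-assignment rule would discard them as ambiguous
            if m:
                eligible = [p for p in range(len(seq)) if not 32 <= p <= 34]
                for pos in rng.choice(eligible, size=min(13 * m, len(eligible)),
                                      replace=False):
                    old = seq[pos]
                    choices = [b for b in "ACGT" if b != old]
                    seq[pos] = choices[int(rng.integers(0, 3))]
            gid = f"nuc-{aa.lower()}{ac}-{m + 1}"
            record = TRNAGeneRecord(gid, "nuclear", aa, ac, "".join(seq))
            if record.sequence in {g.sequence for g in genes}:
                continue  # extremely unlikely collision; drop the copy
            genes.append(record)
            transcripts[gid] = record.sequence + "CCA"
            kinds[gid] = "nuclear"
            members.append(gid)
        families[key] = members
        family_excluded[key] = excluded

    for p in range(config.n_plastid_refs):
        ac = pool.pop()
        aa = _AA_CYCLE[p % len(_AA_CYCLE)]
        seq = _trna_like(rng, ac)
        gid = f"pt-{aa.lower()}{ac}"
        genes.append(TRNAGeneRecord(gid, "plastid", aa, ac, seq))
        transcripts[gid] = seq + "CCA"
        kinds[gid] = "plastid"

    if config.include_identical_pair and mito_seqs:
        gid, seq = mito_seqs[0]
        src = next(g for g in genes if g.gene_id == gid)
        twin = TRNAGeneRecord(f"nuc-twin-of-{gid}", "nuclear", src.amino_acid,
                              src.anticodon, seq)
        genes.append(twin)
        # same transcript sequence; reads from it are inherently ambiguous

    # --- toy mitogenome -----------------------------------------------------
    n = config.genome_length
    genome = list(_random_seq(rng, n))
    features: list[Feature] = []
    cursor = 500

    def embed(seq: str, gap_after: int) -> tuple[int, int]:
        nonlocal cursor
        start = cursor
        genome[start:start + len(seq)] = list(seq)
        cursor = start + len(seq) + gap_after
        return start, start + len(seq)

    for gid, seq in mito_seqs:
        s, e = embed(seq, 400)
        features.append(Feature(f"feat-{gid}", "mito_genome", "tRNA", s, e, "+", gid))

    coding = [("atp6", "protein_coding", 900), ("cob", "protein_coding", 900),
              ("rrn18", "rRNA", 700)]
    boundaries = []
    for name, ftype, length in coding:
        s, e = embed(_random_seq(rng, length), 600)
        features.append(Feature(f"feat-{name}", "mito_genome", ftype, s, e, "+", name))
        boundaries.append(e)

    t_loci: list[tuple[str, int, int, str]] = []
    t_sources: list[str] = []
    for i, b in enumerate(boundaries[:2]):
        seq = _random_seq(rng, int(rng.integers(60, 71)))
        start = b + 60  # within the default 150 bp t-element window
        genome[start:start + len(seq)] = list(seq)
        genome[start + len(seq):start + len(seq) + 3] = list("TTG")  # no genomic CCA
        sid = f"t_element_{i + 1}"
        t_loci.append(("mito_genome", start, start + len(seq), "+"))
        transcripts[sid] = "".join(genome[start:start + len(seq)]) + "CCA"
        kinds[sid] = "t_element"
        t_sources.append(sid)

    orphan_seq = _random_seq(rng, 65)
    orphan_start = n - 2500  # >= 1 kb away from every annotated feature
    genome[orphan_start:orphan_start + 65] = list(orphan_seq)
    genome[orphan_start + 65:orphan_start + 68] = list("TTG")
    orphan = ("mito_genome", orphan_start, orphan_start + 65, "+")
    transcripts["orphan_1"] = orphan_seq + "CCA"
    kinds["orphan_1"] = "orphan"

    genome_str = "".join(genome)
    annotation = GenomeAnnotation(features=features,
                                  seq_lengths={"mito_genome": len(genome_str)})
    refset = build_reference_set(genes)
    return ReferenceUniverse(
        refset=refset, genes=genes, genome={"mito_genome": genome_str},
        annotation=annotation, t_element_loci=t_loci, orphan_locus=orphan,
        transcripts=transcripts, kinds=kinds, families=families,
        family_excluded=family_excluded,
    )


# ---------------------------------------------------------------------------
# library simulation


def _mixture(config: SimulationConfig, universe: ReferenceUniverse,
             rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """Per-fraction mixture proportions over source transcripts."""
    mito_ids = [s for s, k in universe.kinds.items() if k == "mito_trna"]
    nonTrna_ids = [s for s, k in universe.kinds.items() if k in ("t_element", "orphan")]
    plastid_ids = [s for s, k in universe.kinds.items() if k == "plastid"]

    def jitter(n):
        return rng.uniform(0.5, 1.5, size=n)

    mito_w = jitter(len(mito_ids))
    mito_w /= mito_w.sum()
    nt_w = jitter(len(nonTrna_ids)) if nonTrna_ids else np.array([])
    if len(nt_w):
        nt_w /= nt_w.sum()
    plastid_w = jitter(len(plastid_ids)) if plastid_ids else np.array([])
    if len(plastid_w):
        plastid_w /= plastid_w.sum()

    lfc = config.default_import_log2fc()
    fam_keys = list(universe.families)
    fam_w = jitter(len(fam_keys))
    fam_w /= fam_w.sum()
    member_shares: dict[str, float] = {}
    fam_of_member: dict[str, tuple[str, str]] = {}
    for key, w in zip(fam_keys, fam_w):
        members = universe.families[key]
        if not members:
            continue
        shares = jitter(len(members))
        shares /= shares.sum()
        for m, s in zip(members, shares):
            member_shares[m] = w * s
            fam_of_member[m] = key

    # total-cellular proportions
    total: dict[str, float] = {}
    mito_mass = config.mito_total_fraction
    tf = config.t_element_read_fraction
    for sid, w in zip(mito_ids, mito_w):
        total[sid] = mito_mass * (1 - tf) * w
    for sid, w in zip(nonTrna_ids, nt_w):
        total[sid] = mito_mass * tf * w
    for sid, w in zip(plastid_ids, plastid_w):
        total[sid] = config.plastid_total_fraction * w
    nuclear_mass = 1.0 - mito_mass - config.plastid_total_fraction
    for m, s in member_shares.items():
        total[m] = nuclear_mass * s

    # mito-isolate proportions: scale components on the log2 scale, plastid
    # pinned at the configured contamination share
    fam_mult = {key: 2.0 ** l for key, l in zip(fam_keys, lfc)}
    raw: dict[str, float] = {}
    for sid in mito_ids + nonTrna_ids:
        raw[sid] = total[sid] * 2.0 ** config.mito_trna_log2fc
    for m, s in member_shares.items():
        raw[m] = total[m] * fam_mult[fam_of_member[m]]
    z = sum(raw.values())
    scale = (1.0 - config.plastid_contamination_fraction) / z
    mito: dict[str, float] = {sid: v * scale for sid, v in raw.items()}
    for sid, w in zip(plastid_ids, plastid_w):
        mito[sid] = config.plastid_contamination_fraction * w
    return {"mito_isolate": mito, "total_cellular": total}


def _mutate_reads(seq: str, count: int, rate: float, rng: np.random.Generator
                  ) -> list[str]:
    if count == 0:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    reads = np.tile(arr, (count, 1))
    if rate > 0:
        hits = rng.random(reads.shape) < rate
        if hits.any():
            # substitute with an offset of 1-3 in base space: always a change
            idx = np.searchsorted(_BASES, reads[hits])
            offs = rng.integers(1, 4, size=int(hits.sum()))
            reads[hits] = _BASES[(idx + offs) % 4]
    return [bytes(row).decode() for row in reads]


def simulate_libraries(
    config: SimulationConfig,
    universe: ReferenceUniverse,
    rng: np.random.Generator,
    track_provenance: bool = False,
) -> tuple[dict[str, list[str]], SimulationTruth]:
    """Draw multinomial reads per library and report the realized truth."""
    mixtures = _mixture(config, universe, rng)
    source_ids = sorted(universe.transcripts)
    libs = config.libraries()
    reads: dict[str, list[str]] = {}
    truth = SimulationTruth(
        proportions={}, family_log2fc={}, source_log2fc={},
        t_element_loci=list(universe.t_element_loci),
    )
    for lib in libs:
        p = np.array([mixtures[lib.fraction].get(s, 0.0) for s in source_ids])
        p /= p.sum()
        truth.proportions[lib.library_id] = dict(zip(source_ids, p))
        counts = rng.multinomial(config.reads_per_library, p)
        lib_reads: list[str] = []
        provenance: list[str] = []
        for sid, c in zip(source_ids, counts):
            if c == 0:
                continue
            seq = universe.transcripts[sid]
            lib_reads.extend(_mutate_reads(seq, int(c), config.misincorporation_rate, rng))
            if track_provenance:
                provenance.extend([sid] * int(c))
        reads[lib.library_id] = lib_reads
        truth.read_counts[lib.library_id] = {
            s: int(c) for s, c in zip(source_ids, counts) if c}
        if track_provenance:
            truth.provenance[lib.library_id] = provenance

    mito_p = mixtures["mito_isolate"]
    total_p = mixtures["total_cellular"]
    z_m = sum(mito_p.values())
    z_t = sum(total_p.values())
    for sid in source_ids:
        pm, pt = mito_p.get(sid, 0.0) / z_m, total_p.get(sid, 0.0) / z_t
        if pm > 0 and pt > 0:
            truth.source_log2fc[sid] = float(np.log2(pm / pt))
    for key, members in universe.families.items():
        pm = sum(mito_p.get(m, 0.0) for m in members) / z_m
        pt = sum(total_p.get(m, 0.0) for m in members) / z_t
        if pm > 0 and pt > 0:
            truth.family_log2fc[key] = float(np.log2(pm / pt))
    return reads, truth


def truth_report(
    truth: SimulationTruth,
    universe: ReferenceUniverse,
    summaries,
    prediction: Mapping | None = None,
    cca_report=None,
    t_element_fraction: float | None = None,
) -> dict:
    """Recovery metrics: per-family bias/RMSE, import classification agreement,
    and CCA-percentage error vs the configured t-element fraction."""
    import pandas as pd

    rows = []
    for key, true_lfc in truth.family_log2fc.items():
        if key in summaries.index:
            est = float(summaries.at[key, "weighted_log2fc"])
            rows.append({"family": key, "true_log2fc": true_lfc,
                         "estimated_log2fc": est, "error": est - true_lfc})
    fam = pd.DataFrame(rows)
    out = {
        "family_table": fam,
        "bias": float(fam["error"].mean()) if len(fam) else float("nan"),
        "rmse": float(np.sqrt((fam["error"] ** 2).mean())) if len(fam) else float("nan"),
    }
    if prediction is not None:
        agree = total = 0
        for key, info in prediction.items():
            if key not in universe.family_excluded:
                continue
            total += 1
            expected = "excluded" if universe.family_excluded[key] else "imported"
            agree += info["expected"] == expected
        out["classification_agreement"] = agree / total if total else float("nan")
    if cca_report is not None and t_element_fraction is not None:
        pct = cca_report["percentage"].dropna()
        out["cca_percentage_mean"] = float(pct.mean())
        out["cca_percentage_relative_error"] = float(
            abs(pct.mean() - 100.0 * t_element_fraction) / (100.0 * t_element_fraction)
        )
    return out


# ---------------------------------------------------------------------------
# file output


def write_fastq(reads: Sequence[str], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_to_dir(config: SimulationConfig, outdir: str | Path,
                    rng: np.random.Generator | None = None) -> SimulationTruth:
    """Run a full simulation and write FASTA/GFF3/FASTQ/manifest/truth files."""
    from .reference_db import write_gff3, write_reference_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    universe = simulate_references(config, rng)
    reads, truth = simulate_libraries(config, universe, rng)

    write_reference_fasta(universe.refset, outdir / "references.fasta",
                          outdir / "references.tsv")
    with open(outdir / "mito_genome.fasta", "w") as fh:
        for sid, seq in universe.genome.items():
            fh.write(f">{sid}\n{seq}\n")
    write_gff3(universe.annotation, outdir / "mito_genome.gff3")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("library_id\tspecies\tfraction\treplicate\tpath\n")
        for lib in config.libraries():
            fq = outdir / f"{lib.library_id}.fastq"
            write_fastq(reads[lib.library_id], fq)
            fh.write(f"{lib.library_id}\t{lib.species}\t{lib.fraction}\t"
                     f"{lib.replicate}\t{fq}\n")
    with open(outdir / "truth_family_log2fc.tsv", "w") as fh:
        fh.write("amino_acid\tanticodon\ttrue_log2fc\texcluded\n")
        for (aa, ac), v in sorted(truth.family_log2fc.items()):
            fh.write(f"{aa}\t{ac}\t{v:.6f}\t{int(universe.family_excluded[(aa, ac)])}\n")
    return truth
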