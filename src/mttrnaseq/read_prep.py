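"""Length-filter merged reads and collapse identical sequences into read
families with per-library counts.

Reads arrive already merged and adapter-trimmed; quality strings are ignored
after ingestion, and orientation is left as given (resolved at alignment).
"""

from __future__ import annotations

import gzip
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Library",
    "ReadFamily",
    "ConfigurationError",
    "length_filter",
    "collapse",
    "min_count_filter",
    "read_fastq",
    "read_manifest",
    "write_families",
    "DEFAULT_MIN_LEN",
    "DEFAULT_MAX_LEN",
    "DEFAULT_MIN_TOTAL",
]

DEFAULT_MIN_LEN = 50
DEFAULT_MAX_LEN = 95
#: the ">2 reads" / ">=3 reads" rules are numerically identical
DEFAULT_MIN_TOTAL = 3

_DNA = set("ACGT")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Library:
    library_id: str
    species: str
    fraction: str  # "mito_isolate" | "total_cellular"
    replicate: int = 1
    path: str | None = None

    def __post_init__(self):
        if self.fraction not in ("mito_isolate", "total_cellular"):
            raise ConfigurationError(
                f"{self.library_id}: fraction must be mito_isolate or total_cellular"
            )
        if self.replicate < 1:
            raise ConfigurationError(f"{self.library_id}: replicate must be >= 1")


@dataclass
class ReadFamily:
    """A unique read sequence with per-library occurrence counts."""

    family_id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def family_id_for(sequence: str) -> str:
    """Deterministic content-hash identifier so reruns are comparable."""
    return "fam_" + hashlib.sha1(sequence.encode()).hexdigest()[:12]


def length_filter(
    reads: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> Iterator[str]:
    """Yield only reads with ``min_len <= len <= max_len``."""
    if min_len > max_len:
        raise ConfigurationError(f"min_len ({min_len}) > max_len ({max_len})")
    discarded = 0
    for read in reads:
        if min_len <= len(read) <= max_len:
            yield read
        else:
            discarded += 1
    if discarded:
        logger.info("length_filter discarded %d reads", discarded)


def collapse(reads_per_library: Mapping[str, Iterable[str]]) -> list[ReadFamily]:
    """Sum identical reads across libraries into read families.

    Reads containing non-ACGT characters are rejected with a warning (not
    fatal). Output order is deterministic: by decreasing total count, then
    sequence.
    """
    counts: dict[str, dict[str, int]] = {}
    for lib_id, reads in reads_per_library.items():
        rejected = 0
        for read in reads:
            seq = read.upper()
            if set(seq) - _DNA:
                rejected += 1
                continue
            per_lib = counts.setdefault(seq, {})
            per_lib[lib_id] = per_lib.get(lib_id, 0) + 1
        if rejected:
            logger.warning("library %s: rejected %d reads with non-ACGT characters",
                           lib_id, rejected)
    families = [
        ReadFamily(family_id=family_id_for(seq), sequence=seq, counts=dict(per_lib))
        for seq, per_lib in counts.items()
    ]
    families.sort(key=lambda f: (-f.total, f.sequence))
    return families


def min_count_filter(families: Iterable[ReadFamily], min_total: int = DEFAULT_MIN_TOTAL
                     ) -> list[ReadFamily]:
    """Keep families whose count summed over all libraries is >= min_total."""
    if min_total < 1:
        raise ConfigurationError(f"min_total must be >= 1, got {min_total}")
    return [f for f in families if f.total >= min_total]


# ---------------------------------------------------------------------------
# I/O


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzip-compressed or plain)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def read_manifest(path: str | Path) -> list[Library]:
    """Read a run manifest TSV: library_id, species, fraction, replicate, path."""
    libraries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            libraries.append(
                Library(
                    library_id=cols[idx["library_id"]],
                    species=cols[idx["species"]],
                    fraction=cols[idx["fraction"]],
                    replicate=int(cols[idx["replicate"]]),
                    path=cols[idx["path"]] if "path" in idx else None,
                )
            )
    if len({lib.library_id for lib in libraries}) != len(libraries):
        raise ConfigurationError("library_ids in manifest must be unique")
    return libraries


def write_families(families: Iterable[ReadFamily], fasta_path: str | Path,
                   counts_path: str | Path, library_ids: list[str]) -> None:
    """Write collapsed families as FASTA plus a family x library counts TSV."""
    families = list(families)
    with open(fasta_path, "w") as fh:
        for fam in families:
            fh.write(f">{fam.family_id}\n{fam.sequence}\n")
    with open(counts_path, "w") as fh:
        fh.write("family_id\t" + "\t".join(library_ids) + "\n")
        for fam in families:
            row = "\t".join(str(fam.counts.get(lib, 0)) for lib in library_ids)
            fh.write(f"{fam.family_id}\t{row}\n")
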