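import numpy as np
import pytest

from mttrnaseq.read_prep import Library
from mttrnaseq.reference_db import (
    GenomeAnnotation,
    Feature,
    ReferenceSet,
    ReferenceEntry,
    TRNAGeneRecord,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def four_libraries():
    return [
        Library("mito_1", "toy", "mito_isolate", 1),
        Library("mito_2", "toy", "mito_isolate", 2),
        Library("total_1", "toy", "total_cellular", 1),
        Library("total_2", "toy", "total_cellular", 2),
    ]


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def make_refset():
    """Factory for small ReferenceSets from (id, seq[, origin]) tuples."""

    def _make(*entries):
        out = []
        for item in entries:
            rid, seq = item[0], item[1]
            origin = item[2] if len(item) > 2 else "nuclear"
            out.append(ReferenceEntry(
                reference_id=rid, sequence=seq, contributors=(rid,),
                origin=origin, amino_acid="Ala", anticodon="AGC"))
        return ReferenceSet(entries=out)

    return _make


@pytest.fixture
def toy_annotation():
    return GenomeAnnotation(
        features=[
            Feature("trna1", "chrM", "tRNA", 1000, 1075, "+", "mt-alaAGC"),
            Feature("atp6", "chrM", "protein_coding", 2000, 2800, "+", "atp6"),
            Feature("rrn18", "chrM", "rRNA", 5000, 6500, "-", "rrn18"),
        ],
        seq_lengths={"chrM": 10000},
    )


@pytest.fixture
def gene_factory():
    def _make(gene_id, origin="nuclear", amino_acid="Ala", anticodon="AGC",
              sequence=None, is_pseudogene=False):
        if sequence is None:
            rng = np.random.default_rng(abs(hash(gene_id)) % (2**32))
            sequence = random_dna(rng, 75)
        return TRNAGeneRecord(gene_id, origin, amino_acid, anticodon,
                              sequence, is_pseudogene)

    return _make
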