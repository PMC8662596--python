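"""End-to-end orchestration of the standard analysis.

Glue only: every stage is a public operation of its own module. The default
path mirrors the documented workflow: length filter -> collapse -> unique
assignment -> count matrix -> CPM normalization -> expression filter ->
log2 enrichment -> anticodon summaries -> import prediction and test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import import_analysis, mapper, quantify, read_prep
from .read_prep import Library, ReadFamily
from .reference_db import ReferenceSet, TRNAGeneRecord, anticodon_inventory

__all__ = ["EnrichmentRun", "run_enrichment"]


@dataclass
class EnrichmentRun:
    families: list[ReadFamily]
    assignments: list[mapper.Assignment]
    counts: pd.DataFrame
    mapping_summary: pd.DataFrame
    factors: pd.Series
    norm: pd.DataFrame
    results: pd.DataFrame  # per-reference log2fc for references passing the filter
    summaries: pd.DataFrame  # per nuclear anticodon family
    depletion: quantify.DepletionSummary
    prediction: dict | None = None
    import_test: import_analysis.ImportTestResult | None = None


def run_enrichment(
    reads_per_library: Mapping[str, Iterable[str]],
    refs: ReferenceSet,
    libraries: Sequence[Library],
    mito_genes: Sequence[TRNAGeneRecord] | None = None,
    min_len: int = read_prep.DEFAULT_MIN_LEN,
    max_len: int = read_prep.DEFAULT_MAX_LEN,
    min_identity: float = mapper.DEFAULT_MIN_IDENTITY,
    min_coverage: float = mapper.DEFAULT_MIN_COVERAGE,
    min_cpm: float = quantify.DEFAULT_MIN_CPM,
    normalization: str = "none",
    pseudocount: float = quantify.DEFAULT_PSEUDOCOUNT_CPM,
) -> EnrichmentRun:
    """Run the enrichment analysis from raw merged reads to the import test."""
    filtered = {
        lib_id: read_prep.length_filter(reads, min_len, max_len)
        for lib_id, reads in reads_per_library.items()
    }
    families = read_prep.collapse(filtered)
    index = mapper.ReferenceIndex(refs)
    assignments = [
        mapper.assign_family(fam, refs, min_identity, min_coverage, index=index)
        for fam in families
    ]
    counts, mapping_summary = mapper.build_count_matrix(
        assignments, families, libraries, refs)
    factors = quantify.scale_factors(counts, method=normalization) \
        if normalization != "none" else pd.Series(1.0, index=counts.columns)
    norm = quantify.cpm_normalize(counts, factors)
    passed = quantify.expression_filter(norm, libraries, min_cpm=min_cpm)
    results = quantify.log2_enrichment(norm.loc[passed], libraries,
                                       pseudocount=pseudocount)

    membership = {
        e.reference_id: (e.amino_acid, e.anticodon)
        for e in refs if e.origin == "nuclear"
    }
    summaries = quantify.anticodon_weighted_enrichment(results, membership)
    origins = {e.reference_id: e.origin for e in refs}
    depletion = quantify.compartment_depletion(results, origins)

    prediction = None
    import_test = None
    if mito_genes is not None:
        inventory = anticodon_inventory(
            [g for g in mito_genes if g.origin == "mitochondrial"])
        prediction = import_analysis.predict_import_status(
            list(summaries.index), inventory)
        import_test = import_analysis.test_import_separation(summaries, prediction)

    return EnrichmentRun(
        families=families, assignments=assignments, counts=counts,
        mapping_summary=mapping_summary, factors=factors, norm=norm,
        results=results, summaries=summaries, depletion=depletion,
        prediction=prediction, import_test=import_test,
    )
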