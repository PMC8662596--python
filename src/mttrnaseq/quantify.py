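"""Normalization, expression filtering and enrichment statistics.

Count matrices are pandas DataFrames (rows = reference_ids, columns =
library_ids). The log2 enrichment estimator is a pseudocount ratio of mean
CPMs between the mito-isolate and total-cellular fractions; per-anticodon
summaries weight each member sequence by its share of family CPM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .read_prep import Library

__all__ = [
    "scale_factors",
    "cpm_normalize",
    "expression_filter",
    "log2_enrichment",
    "anticodon_weighted_enrichment",
    "compartment_depletion",
    "collapse_sum_groups",
    "DEFAULT_MIN_CPM",
    "DEFAULT_PSEUDOCOUNT_CPM",
]

DEFAULT_MIN_CPM = 2.0
DEFAULT_PSEUDOCOUNT_CPM = 0.5


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, obs_size: float, ref_size: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Trimmed mean of M-values (log2 scale factor) of obs vs ref library."""
    mask = (obs > 0) & (ref > 0)
    obs_p = obs[mask] / obs_size
    ref_p = ref[mask] / ref_size
    m = np.log2(obs_p / ref_p)
    a = 0.5 * np.log2(obs_p * ref_p)
    # asymptotic (delta-method) binomial variance of M
    w = (obs_size - obs[mask]) / (obs_size * obs[mask]) \
        + (ref_size - ref[mask]) / (ref_size * ref[mask])
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(f) if np.isfinite(f) else 0.0


def scale_factors(counts: pd.DataFrame, method: str = "trimmed-mean-of-M") -> pd.Series:
    """Per-library scale factors (effective size = raw size * factor).

    ``trimmed-mean-of-M``: each library is compared to a reference library
    (the one whose 75th-percentile CPM is closest to the mean of those
    quantiles); gene-wise log-ratios M and abundances A are computed over rows
    nonzero in both, 30% of M and 5% of A are trimmed from each tail, and the
    precision-weighted mean of the remaining M gives the log2 factor. Factors
    are re-centered to geometric mean 1. ``none`` returns all ones.
    """
    if counts.shape[1] < 2:
        raise ValueError("scale_factors requires >= 2 libraries")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    sizes = counts.sum(axis=0)
    zero = sizes[sizes == 0]
    if len(zero):
        raise ValueError(f"library with all-zero counts: {list(zero.index)}")
    if method == "none":
        return pd.Series(1.0, index=counts.columns)
    if method != "trimmed-mean-of-M":
        raise ValueError(f"unknown method {method!r}")

    cpm = counts.div(sizes, axis=1) * 1e6
    q75 = cpm.quantile(0.75)
    ref_lib = (q75 - q75.mean()).abs().idxmin()
    ref = counts[ref_lib].to_numpy(dtype=float)
    ref_size = float(sizes[ref_lib])
    log_factors = {}
    for lib in counts.columns:
        if lib == ref_lib:
            log_factors[lib] = 0.0
            continue
        log_factors[lib] = _tmm_pair(counts[lib].to_numpy(dtype=float), ref,
                                     float(sizes[lib]), ref_size)
    factors = pd.Series({lib: 2.0 ** f for lib, f in log_factors.items()})[counts.columns]
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def cpm_normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on effective library sizes (column sum * factor)."""
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    if (factors <= 0).any():
        raise ValueError("scale factors must be positive")
    eff = counts.sum(axis=0) * factors
    return counts.div(eff, axis=1) * 1e6


def expression_filter(
    norm: pd.DataFrame,
    libraries: Sequence[Library],
    min_cpm: float = DEFAULT_MIN_CPM,
    min_libraries: int | None = None,
) -> pd.Index:
    """References with CPM >= min_cpm in at least ``min_libraries`` libraries.

    The default ``min_libraries`` is the size of the smaller fraction group.
    """
    lib_ids = [lib.library_id for lib in libraries]
    if min_libraries is None:
        groups = pd.Series([lib.fraction for lib in libraries]).value_counts()
        min_libraries = int(groups.min())
    if min_libraries > len(lib_ids):
        raise ValueError("min_libraries exceeds the number of libraries")
    ok = (norm[lib_ids] >= min_cpm).sum(axis=1) >= min_libraries
    return norm.index[ok]


def log2_enrichment(
    norm: pd.DataFrame,
    libraries: Sequence[Library],
    pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM,
) -> pd.DataFrame:
    """Per-reference log2 fold-change, mito-isolate vs total-cellular.

    log2fc = log2((mean mito CPM + c) / (mean total CPM + c)), c in CPM units.
    Returns columns log2fc, mean_cpm (grand mean over all libraries),
    mito_mean_cpm, total_mean_cpm.
    """
    mito = [lib.library_id for lib in libraries if lib.fraction == "mito_isolate"]
    total = [lib.library_id for lib in libraries if lib.fraction == "total_cellular"]
    if not mito or not total:
        raise ValueError("need >= 1 library in each fraction")
    mito_mean = norm[mito].mean(axis=1)
    total_mean = norm[total].mean(axis=1)
    lfc = np.log2((mito_mean + pseudocount) / (total_mean + pseudocount))
    return pd.DataFrame({
        "log2fc": lfc,
        "mean_cpm": norm[mito + total].mean(axis=1),
        "mito_mean_cpm": mito_mean,
        "total_mean_cpm": total_mean,
    })


def anticodon_weighted_enrichment(
    results: pd.DataFrame,
    membership: Mapping[str, tuple],
    weight_column: str = "mean_cpm",
) -> pd.DataFrame:
    """Expression-weighted mean log2fc per anticodon (isodecoder) family.

    ``membership`` maps reference_id -> family key, typically
    (amino_acid, anticodon) or (amino_acid, anticodon, origin). Weights are
    each member's share of summed family CPM (``weight_column``; the default
    uses mean CPM across all libraries, configurable to e.g. total-cellular
    CPM only). Families with no surviving members are omitted.
    """
    rows = []
    keys = {}
    for rid in results.index:
        if rid in membership:
            keys.setdefault(membership[rid], []).append(rid)
    for key, members in keys.items():
        sub = results.loc[members]
        total = float(sub[weight_column].sum())
        if total <= 0:
            weights = np.full(len(sub), 1.0 / len(sub))
        else:
            weights = (sub[weight_column] / total).to_numpy()
        rows.append({
            "family": key,
            "weighted_log2fc": float(np.sum(weights * sub["log2fc"].to_numpy())),
            "total_family_cpm": total,
            "n_members": len(members),
            "member_references": tuple(members),
            "member_weights": tuple(float(w) for w in weights),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("family")
    return df


@dataclass
class DepletionSummary:
    mean_mt_log2fc: float
    mean_nuclear_log2fc: float
    mean_plastid_log2fc: float
    nuclear_depletion: float
    plastid_depletion: float


def compartment_depletion(results: pd.DataFrame, origins: Mapping[str, str]
                          ) -> DepletionSummary:
    """Unweighted per-origin means and depletion relative to the mt class.

    ``origins`` maps reference_id to one of mitochondrial / nuclear / plastid;
    mitochondrial stem-loop references should be labeled mitochondrial so they
    contribute to the mt mean. depletion = mean(class) - mean(mt), negative
    when the class is depleted relative to mt references.
    """
    by_class: dict[str, list[float]] = {"mitochondrial": [], "nuclear": [], "plastid": []}
    for rid in results.index:
        origin = origins.get(rid)
        if origin in by_class:
            by_class[origin].append(float(results.at[rid, "log2fc"]))
    means = {k: (float(np.mean(v)) if v else float("nan")) for k, v in by_class.items()}
    return DepletionSummary(
        mean_mt_log2fc=means["mitochondrial"],
        mean_nuclear_log2fc=means["nuclear"],
        mean_plastid_log2fc=means["plastid"],
        nuclear_depletion=means["nuclear"] - means["mitochondrial"],
        plastid_depletion=means["plastid"] - means["mitochondrial"],
    )


def collapse_sum_groups(counts: pd.DataFrame, groups: Mapping[str, Sequence[str]]
                        ) -> pd.DataFrame:
    """Sum declared groups of rows (e.g. non-identical fMet copies) before
    normalization; the group id replaces its member rows."""
    out = counts.copy()
    for group_id, members in groups.items():
        members = [m for m in members if m in out.index]
        if not members:
            continue
        summed = out.loc[members].sum(axis=0)
        out = out.drop(index=members)
        out.loc[group_id] = summed
    return out.astype(counts.dtypes.iloc[0] if len(counts.dtypes) else np.int64)
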