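"""Prediction and testing of cytosolic tRNA import vs exclusion.

A cytosolic anticodon family is predicted *excluded* when an intact
mitochondrial gene decodes the same codons (literal anticodon match after U/T
normalization, with the documented CAU decoding-class rules) and *imported*
otherwise. Group separation is assessed with Welch's t-test on
expression-weighted family enrichments; cross-species gene-loss shifts are
flagged when every species lacking the mt gene exceeds every outgroup.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference_db import AnticodonInventory, normalize_anticodon

logger = logging.getLogger(__name__)

__all__ = [
    "ImportTestResult",
    "predict_import_status",
    "welch_t_test",
    "test_import_separation",
    "gene_loss_shift",
]


@dataclass(frozen=True)
class ImportTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    status: str = "ok"  # "ok" | "na"

    @property
    def direction(self) -> float:
        return self.mean_a - self.mean_b


def _match_key(amino_acid: str, anticodon: str, decoding_class: str) -> tuple[str, str]:
    """Key under which a mito inventory entry blocks (excludes) a cytosolic family.

    Non-CAU anticodons match literally. For CAU: a lysidine-modified mt
    Ile(CAU) decodes AUA and therefore matches cytosolic Ile(UAU); elongator
    Met(CAU) matches cytosolic elongator Met(CAU); the organellar initiator
    (fMet) matches the cytosolic initiator.
    """
    ac = normalize_anticodon(anticodon)
    if ac != "CAU":
        return ("*", ac)
    if decoding_class == "Ile-lysidine":
        return ("Ile", "UAU")
    if decoding_class == "elongator-Met":
        return ("Met", "CAU")
    return ("initiator", "CAU")


def _family_key(family: tuple) -> tuple[str, str]:
    """Matching key for a cytosolic family (amino_acid, anticodon[, class])."""
    amino_acid, anticodon = family[0], family[1]
    ac = normalize_anticodon(anticodon)
    if ac == "CAU":
        if amino_acid in ("iMet", "fMet") or (len(family) > 2 and
                                              family[2] == "initiator/fMet"):
            return ("initiator", "CAU")
        if amino_acid == "Met":
            return ("Met", "CAU")
        if amino_acid == "Ile":
            # cytosolic Ile(CAU) would itself be lysidine-class; match as AUA decoder
            return ("Ile", "UAU")
        raise ValueError(f"cannot interpret CAU family {family!r}")
    if amino_acid in ("Ile",) and ac == "UAU":
        return ("Ile", "UAU")
    return ("*", ac)


def predict_import_status(
    nuclear_families: Sequence[tuple],
    inventory: AnticodonInventory,
) -> dict[tuple, dict]:
    """Predict imported/excluded per cytosolic family from the mito inventory.

    Families with undetermined anticodons (e.g. tRNA-Sec "NNN") are skipped
    with a logged notice. Returns family -> {"expected", "basis"}.
    """
    blocked: dict[tuple[str, str], tuple] = {}
    for aa, ac, dc in sorted(inventory.entries):
        blocked[_match_key(aa, ac, dc)] = (aa, ac, dc)

    out: dict[tuple, dict] = {}
    for family in nuclear_families:
        anticodon = str(family[1]).upper()
        if any(b not in "ACGUT" for b in anticodon):
            logger.info("skipping family %r with undetermined anticodon", family)
            continue
        key = _family_key(family)
        basis = blocked.get(key)
        if basis is None and key[0] != "*":
            # amino-acid-specific key may also be blocked by a literal match
            basis = blocked.get(("*", key[1]))
        out[family] = {
            "expected": "excluded" if basis is not None else "imported",
            "basis": basis,
        }
    return out


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> ImportTestResult:
    """Welch's unequal-variance t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group must have size >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise ValueError("degenerate test: zero variance in both groups, equal means")
        t = math.inf if a.mean() > b.mean() else -math.inf
        return ImportTestResult(t, float(a.size + b.size - 2), 0.0,
                                a.size, b.size, float(a.mean()), float(b.mean()))
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    res = stats.ttest_ind(a, b, equal_var=False)
    return ImportTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(df),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def test_import_separation(
    summaries: pd.DataFrame,
    prediction: Mapping[tuple, Mapping],
) -> ImportTestResult:
    """Welch test of weighted_log2fc between predicted-imported and -excluded
    families. Direction = imported mean - excluded mean. Returns an NA result
    when either class has fewer than two families."""
    imported, excluded = [], []
    for family, info in prediction.items():
        if family not in summaries.index:
            continue
        value = float(summaries.at[family, "weighted_log2fc"])
        (imported if info["expected"] == "imported" else excluded).append(value)
    if len(imported) < 2 or len(excluded) < 2:
        return ImportTestResult(
            t_statistic=float("nan"), degrees_of_freedom=float("nan"),
            p_value=float("nan"), n_a=len(imported), n_b=len(excluded),
            mean_a=float(np.mean(imported)) if imported else float("nan"),
            mean_b=float(np.mean(excluded)) if excluded else float("nan"),
            status="na",
        )
    return welch_t_test(imported, excluded)


def gene_loss_shift(
    species_summaries: Mapping[str, pd.DataFrame],
    species_inventories: Mapping[str, AnticodonInventory],
    outgroups: Sequence[str],
    strict: bool = True,
) -> pd.DataFrame:
    """Flag anticodon families whose enrichment rose with mt gene loss.

    For each family lost in >= 1 focal species (mt gene absent there, present
    in >= 1 outgroup), ``loss_associated_gain`` is true iff every loser
    species' weighted_log2fc exceeds every outgroup's (strictly by default);
    ``loss_associated_drop`` reports the converse. Species whose summaries
    lack the family are recorded NA and excluded from the quantifier with a
    warning.
    """
    if not outgroups:
        raise ValueError("need >= 1 outgroup species")
    focal = [sp for sp in species_summaries if sp not in outgroups]
    blocked_by_species = {
        sp: {(_match_key(aa, ac, dc)) for aa, ac, dc in inv.entries}
        for sp, inv in species_inventories.items()
    }
    families = sorted({fam for df in species_summaries.values() for fam in df.index})
    rows = []
    for family in families:
        key = _family_key(family)
        has_gene = {sp: (key in blocked_by_species.get(sp, set())
                         or (key[0] != "*" and ("*", key[1]) in blocked_by_species.get(sp, set())))
                    for sp in species_summaries}
        losers = [sp for sp in focal if not has_gene[sp]]
        if not losers or not any(has_gene[og] for og in outgroups):
            continue

        def value(sp):
            df = species_summaries[sp]
            return float(df.at[family, "weighted_log2fc"]) if family in df.index else float("nan")

        loser_vals = {sp: value(sp) for sp in losers}
        out_vals = {og: value(og) for og in outgroups}
        usable_losers = {sp: v for sp, v in loser_vals.items() if not math.isnan(v)}
        usable_out = {og: v for og, v in out_vals.items() if not math.isnan(v)}
        for sp, v in {**loser_vals, **out_vals}.items():
            if math.isnan(v):
                logger.warning("family %r missing from summaries of %s; excluded "
                               "from the all-species quantifier", family, sp)
        if usable_losers and usable_out:
            if strict:
                gain = all(lv > ov for lv in usable_losers.values()
                           for ov in usable_out.values())
                drop = all(lv < ov for lv in usable_losers.values()
                           for ov in usable_out.values())
            else:
                gain = all(lv >= ov for lv in usable_losers.values()
                           for ov in usable_out.values())
                drop = all(lv <= ov for lv in usable_losers.values()
                           for ov in usable_out.values())
        else:
            gain = drop = False
        rows.append({
            "family": family,
            "lost_in": tuple(losers),
            "loser_values": tuple(loser_vals[sp] for sp in losers),
            "outgroup_values": tuple(out_vals[og] for og in outgroups),
            "loss_associated_gain": gain,
            "loss_associated_drop": drop,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("family")
    return df
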