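import numpy as np
import pytest

from mttrnaseq.mapper import (
    AlignmentHit,
    Assignment,
    GenomeIndex,
    ReferenceIndex,
    Scoring,
    align,
    assign_family,
    build_count_matrix,
    contaminant_screen,
    map_to_genome,
    revcomp,
)
from mttrnaseq.read_prep import ReadFamily, collapse
from tests.conftest import random_dna

# ---------------------------------------------------------------------------
# independent quadratic-time oracle (full-matrix local alignment, documented
# conventions re-implemented from scratch: best cell = first maximum in
# row-major order; traceback prefers diagonal, then up, then left)


def oracle_align_oriented(q, r, match=1, mismatch=-1, gap=-2):
    n, m = len(q), len(r)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            v = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            H[i][j] = v
            if v > best:
                best, bi, bj = v, i, j
    i, j = bi, bj
    cols = matches = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = match if q[i - 1] == r[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += q[i - 1] == r[j - 1]
            cols += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return {"score": best, "q": (i, bi), "r": (j, bj), "cols": cols,
            "matches": matches}


def oracle_align(q, r, match=1, mismatch=-1, gap=-2, min_score=30):
    fwd = oracle_align_oriented(q, r, match, mismatch, gap)
    rev = oracle_align_oriented(revcomp(q), r, match, mismatch, gap)
    if rev["score"] > fwd["score"]:
        n = len(q)
        qs, qe = rev["q"]
        rev["q"] = (n - qe, n - qs)
        rev["strand"] = "-"
        out = rev
    else:
        fwd["strand"] = "+"
        out = fwd
    if out["score"] < min_score:
        return None
    out["identity"] = 100.0 * out["matches"] / out["cols"] if out["cols"] else 0.0
    out["coverage"] = 100.0 * (out["q"][1] - out["q"][0]) / len(q)
    return out


def _random_pair(rng):
    """Query/reference pairs spanning exact, mutated, indel and unrelated cases."""
    kind = rng.integers(0, 4)
    ref = random_dna(rng, int(rng.integers(60, 96)))
    if kind == 0:
        return ref, ref
    if kind == 1:  # substitutions
        q = list(ref)
        for pos in rng.choice(len(q), size=int(rng.integers(1, 9)), replace=False):
            q[pos] = "ACGT"[int(rng.integers(0, 4))]
        return "".join(q), ref
    if kind == 2:  # indels + substitutions
        q = list(ref)
        for _ in range(int(rng.integers(1, 4))):
            pos = int(rng.integers(1, len(q) - 1))
            if rng.integers(0, 2):
                del q[pos]
            else:
                q.insert(pos, "ACGT"[int(rng.integers(0, 4))])
        return "".join(q)[: 95], ref
    return random_dna(rng, int(rng.integers(50, 96))), ref  # unrelated


class TestAlignOracleEquivalence:
    def test_oracle_equivalence_200_random_pairs(self):
        rng = np.random.default_rng(42)
        for trial in range(200):
            q, ref = _random_pair(rng)
            got = align(q, ref)
            want = oracle_align(q, ref)
            if want is None:
                assert got is None, (trial, q, ref)
                continue
            assert got is not None, (trial, q, ref)
            assert got.score == want["score"], (trial, q, ref)
            assert got.identity_pct == pytest.approx(want["identity"], abs=1e-12)
            assert got.coverage_pct == pytest.approx(want["coverage"], abs=1e-12)
            assert got.query_interval == want["q"]
            assert got.reference_interval == want["r"]
            assert got.strand == want["strand"]


class TestAlign:
    def test_identity_case(self, rng):
        ref = random_dna(rng, 72)
        hit = align(ref, ref)
        assert hit.identity_pct == 100.0
        assert hit.coverage_pct == 100.0
        assert hit.score == 72
        assert hit.strand == "+"

    def test_six_substitutions_identity(self, rng):
        # 70 nt with 6 interior, well-spaced substitutions: identity 100*64/70
        ref = random_dna(rng, 70)
        q = list(ref)
        for pos in (5, 15, 25, 35, 45, 55):
            q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
        hit = align("".join(q), ref)
        assert hit.identity_pct == pytest.approx(100.0 * 64 / 70)
        assert hit.coverage_pct == 100.0
        want = oracle_align("".join(q), ref)
        assert hit.score == want["score"]

    def test_reverse_complement_strand_symmetry(self, rng):
        ref = random_dna(rng, 70)
        fwd = align(ref, ref)
        rev = align(revcomp(ref), ref)
        assert rev.strand == "-"
        assert rev.identity_pct == fwd.identity_pct
        assert rev.coverage_pct == fwd.coverage_pct
        assert rev.score == fwd.score

    def test_below_floor_returns_none(self):
        assert align("ACGTACGTACGTACGTACGTACGT", "TTTTGGGGTTTTGGGGTTTT") is None

    def test_non_acgt_reference_rejected(self):
        with pytest.raises(ValueError):
            align("ACGTACGT", "ACGTNACGT")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align("", "ACGT")


def _mutate(ref, n_subs, start=4, spacing=None):
    """Interior substitutions, spaced so end-trimming is never optimal."""
    if n_subs == 0:
        return ref
    q = list(ref)
    spacing = spacing or max(4, (len(ref) - 8) // max(n_subs, 1))
    positions = [start + i * spacing for i in range(n_subs)]
    assert positions[-1] < len(ref) - 4
    for pos in positions:
        q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
    return "".join(q)


class TestAssignFamily:
    def _family(self, seq):
        return ReadFamily(family_id="f", sequence=seq, counts={"lib": 1})

    def test_identity_below_threshold_unmapped(self, rng, make_refset):
        ref = random_dna(rng, 80)
        q = _mutate(ref, 9, spacing=8)  # identity 100*71/80 = 88.75 < 90
        refs = make_refset(("r1", ref))
        a = assign_family(self._family(q), refs)
        assert a.status == "unmapped"

    def test_identity_at_threshold_assigned(self, rng, make_refset):
        ref = random_dna(rng, 80)
        q = _mutate(ref, 8, spacing=9)  # identity 100*72/80 = 90.0
        refs = make_refset(("r1", ref))
        a = assign_family(self._family(q), refs)
        assert a.status == "assigned"
        assert a.best_hit.identity_pct == pytest.approx(90.0)

    def test_coverage_boundary(self, rng, make_refset):
        ref = random_dna(rng, 90)
        refs = make_refset(("r1", ref))
        # 64 of 80 query bases from the reference, tail guaranteed mismatching
        tail = "".join({"A": "C", "C": "G", "G": "T", "T": "A"}[b]
                       for b in ref[64:80])
        q80 = ref[:64] + tail  # coverage 100*64/80 = 80.0
        a = assign_family(self._family(q80), refs)
        assert a.status == "assigned"
        assert a.best_hit.coverage_pct == pytest.approx(80.0)
        tail = "".join({"A": "C", "C": "G", "G": "T", "T": "A"}[b]
                       for b in ref[63:80])
        q79 = ref[:63] + tail  # coverage 100*63/80 = 78.75 < 80
        a = assign_family(self._family(q79), refs)
        assert a.status == "unmapped"

    def test_two_passing_references_ambiguous(self, rng, make_refset):
        ref = random_dna(rng, 80)
        near = _mutate(ref, 2)  # within 90% identity of ref
        refs = make_refset(("r1", ref), ("r2", near))
        a = assign_family(self._family(ref), refs)
        assert a.status == "ambiguous"
        assert a.reference_id is None

    def test_single_passing_hit_assigned(self, rng, make_refset):
        ref = random_dna(rng, 60)
        q = _mutate(ref, 3, spacing=15)  # identity 95, coverage 100
        refs = make_refset(("r1", ref), ("r2", random_dna(rng, 60)))
        a = assign_family(self._family(q), refs)
        assert a.status == "assigned"
        assert a.reference_id == "r1"
        assert a.best_hit.identity_pct == pytest.approx(95.0)

    def test_ambiguous_origin_flagged(self, rng, make_refset):
        seq = random_dna(rng, 75)
        refs = make_refset(("nuc_r", seq, "nuclear"), ("mt_r", seq, "mitochondrial"))
        a = assign_family(self._family(seq), refs)
        assert a.status == "ambiguous"
        assert a.ambiguous_origin

    def test_threshold_monotonicity(self, rng, make_refset):
        refs = make_refset(*[(f"r{i}", random_dna(rng, 78)) for i in range(6)])
        fams = [self._family(_mutate(refs.by_id(f"r{i % 6}").sequence,
                                     int(rng.integers(0, 8)), spacing=8))
                for i in range(30)]
        def assigned(min_id, min_cov):
            return {f.family_id + f.sequence for f in fams
                    if assign_family(f, refs, min_id, min_cov).status == "assigned"}
        base = assigned(90, 80)
        assert assigned(95, 80) <= base
        assert assigned(90, 90) <= base

    def test_index_matches_exhaustive(self, rng, make_refset):
        refs = make_refset(*[(f"r{i}", random_dna(rng, 80)) for i in range(8)])
        index = ReferenceIndex(refs)
        for i in range(40):
            ref = refs.by_id(f"r{int(rng.integers(0, 8))}").sequence
            q = _mutate(ref, int(rng.integers(0, 8)), spacing=9)
            if rng.integers(0, 2):
                q = revcomp(q)
            a1 = assign_family(ReadFamily("f", q, {"l": 1}), refs, index=index)
            a2 = assign_family(ReadFamily("f", q, {"l": 1}), refs)
            assert (a1.status, a1.reference_id) == (a2.status, a2.reference_id)


class TestMapToGenome:
    def test_duplicated_locus_gives_two_hits(self, rng):
        insert = random_dna(rng, 70)
        genome = (random_dna(rng, 300) + insert + random_dna(rng, 400)
                  + insert + random_dna(rng, 300))
        fam = ReadFamily("f", insert, {"l": 3})
        hits = map_to_genome(fam, genome)
        assert len(hits) == 2
        starts = sorted(h.reference_interval[0] for h in hits)
        assert starts == [300, 770]

    def test_divergent_read_no_hits(self, rng):
        genome = random_dna(rng, 2000)
        fam = ReadFamily("f", random_dna(rng, 80), {"l": 3})
        assert map_to_genome(fam, genome) == []

    def test_four_substitutions_identity_95(self, rng):
        locus = random_dna(rng, 80)
        genome = random_dna(rng, 500) + locus + random_dna(rng, 500)
        q = _mutate(locus, 4, spacing=18)
        hits = map_to_genome(ReadFamily("f", q, {"l": 3}), genome)
        assert len(hits) == 1
        assert hits[0].identity_pct == pytest.approx(95.0)
        want = oracle_align(q, locus)
        assert hits[0].score == want["score"]

    def test_reverse_strand_locus(self, rng):
        locus = random_dna(rng, 72)
        genome = random_dna(rng, 200) + locus + random_dna(rng, 200)
        hits = map_to_genome(ReadFamily("f", revcomp(locus), {"l": 3}), genome)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].reference_interval == (200, 272)

    def test_shared_index_equivalent(self, rng):
        genome = {"chrM": random_dna(rng, 3000)}
        fam = ReadFamily("f", genome["chrM"][100:175], {"l": 3})
        index = GenomeIndex(genome)
        assert map_to_genome(fam, genome, index=index) == map_to_genome(fam, genome)


class TestBuildCountMatrix:
    def _setup(self, four_libraries, make_refset, rng):
        refs = make_refset(("R", random_dna(rng, 70)), ("S", random_dna(rng, 70)))
        fams = [
            ReadFamily("f1", "A" * 60, {"mito_1": 2}),
            ReadFamily("f2", "C" * 60, {"mito_1": 3, "total_1": 4}),
            ReadFamily("f3", "G" * 60, {"mito_1": 5}),
        ]
        assignments = [
            Assignment("f1", "assigned", "R"),
            Assignment("f2", "assigned", "R"),
            Assignment("f3", "ambiguous"),
        ]
        return refs, fams, assignments

    def test_summation(self, four_libraries, make_refset, rng):
        refs, fams, assignments = self._setup(four_libraries, make_refset, rng)
        counts, summary = build_count_matrix(assignments, fams, four_libraries, refs)
        assert counts.at["R", "mito_1"] == 5
        assert counts.at["R", "total_1"] == 4
        assert counts.at["S", "mito_1"] == 0
        assert summary.at["ambiguous", "mito_1"] == 5

    def test_empty_assignments_full_index(self, four_libraries, make_refset, rng):
        refs = make_refset(("R", random_dna(rng, 70)))
        counts, _ = build_count_matrix([], [], four_libraries, refs)
        assert list(counts.index) == ["R"]
        assert (counts.to_numpy() == 0).all()
        assert list(counts.columns) == [l.library_id for l in four_libraries]

    def test_determinism_byte_identical(self, four_libraries, make_refset, rng, tmp_path):
        refs, fams, assignments = self._setup(four_libraries, make_refset, rng)
        outs = []
        for i in range(2):
            counts, _ = build_count_matrix(assignments, fams, four_libraries, refs)
            p = tmp_path / f"c{i}.tsv"
            counts.to_csv(p, sep="\t")
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]


class TestContaminantScreen:
    def test_contaminant_only_hit(self, rng, make_refset):
        bacterial = random_dna(rng, 76)
        plant = make_refset(("p1", random_dna(rng, 76)))
        contam = make_refset(("c1", bacterial, "contaminant"))
        fam = ReadFamily("f", _mutate(bacterial, 1), {"l": 5})
        labels = contaminant_screen([fam], plant, contam)
        assert labels == {"f": "contaminant"}

    def test_empty_contaminant_set(self, rng, make_refset):
        plant = make_refset(("p1", random_dna(rng, 76)))
        contam = make_refset()
        fam = ReadFamily("f", random_dna(rng, 70), {"l": 5})
        labels = contaminant_screen([fam], plant, contam)
        assert labels["f"] == "unknown"

    def test_below_threshold_bypasses(self, rng, make_refset):
        plant = make_refset(("p1", random_dna(rng, 76)))
        contam = make_refset(("c1", random_dna(rng, 76), "contaminant"))
        fam = ReadFamily("f", contam.by_id("c1").sequence, {"l": 2})
        assert contaminant_screen([fam], plant, contam) == {}

    def test_both_hits_kept_as_plant(self, rng, make_refset):
        seq = random_dna(rng, 76)
        plant = make_refset(("p1", seq))
        contam = make_refset(("c1", seq, "contaminant"))
        fam = ReadFamily("f", seq, {"l": 5})
        assert contaminant_screen([fam], plant, contam) == {"f": "plant"}
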