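"""Aligner and classification behaviour, checked against a full dynamic-
programming oracle and the classification truth table."""

import numpy as np
import pytest

from oryzaloss import mapping as mp
from oryzaloss import seqs
from oryzaloss import synthetic_data as sd


def sw_affine_score(q, r, match=1, mismatch=-2, gap_open=-5, gap_ext=-2):
    """Independent pure-Python Smith-Waterman (affine gaps, same scoring
    convention: a gap of length L costs open + L * extend)."""
    n, m = len(q), len(r)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_ext, E[i][j - 1] + gap_ext)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_ext, F[i - 1][j] + gap_ext)
            s = match if q[i - 1] == r[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def mutate(codes, rate, rng, indel=False):
    out = codes.copy()
    hit = rng.random(codes.size) < rate
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    if indel:
        p = int(rng.integers(10, codes.size - 10))
        out = np.concatenate((out[:p], out[p + 3 :]))  # 3 bp deletion
    return out


class TestAlignLocal:
    def test_exact_substring_perfect_hit(self, small_genome, small_index):
        q = small_genome.codes[10_000:10_600].copy()
        hits = mp.align_local(q, small_index)
        assert hits
        h = hits[0]
        assert h.identity == 1.0 and h.coverage == 1.0
        assert h.ref_start == 10_000 and h.ref_end == 10_600

    def test_mutated_query_recovered_at_locus(self, small_genome, small_index, rng):
        q = mutate(small_genome.codes[50_000:50_700].copy(), 0.025, rng)
        h = mp.align_local(q, small_index)[0]
        assert abs(h.ref_start - 50_000) < 50
        assert h.identity == pytest.approx(0.975, abs=0.02)

    def test_query_shorter_than_seed_gives_no_hits(self, small_index):
        assert mp.align_local(np.zeros(8, np.uint8), small_index) == []

    @pytest.mark.parametrize("case_seed", [0, 1, 2, 3])
    def test_best_score_equals_smith_waterman_oracle(self, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        ref = rng.integers(0, 4, size=900).astype(np.uint8)
        start = int(rng.integers(0, 600))
        q = mutate(ref[start : start + 250].copy(), 0.05, rng, indel=(case_seed % 2 == 0))
        index = mp.ReferenceIndex.build([("ref", ref)], k=13)
        hits = mp.align_local(q, index)
        assert hits
        oracle = sw_affine_score(q.tolist(), ref.tolist())
        # reverse strand cannot beat the planted forward alignment here
        assert hits[0].score == oracle

    def test_strand_symmetry(self, small_genome, small_index, rng):
        q = mutate(small_genome.codes[200_000:200_500].copy(), 0.03, rng)
        fwd = mp.align_local(q, small_index)[0]
        rev = mp.align_local(seqs.revcomp(q), small_index)[0]
        assert fwd.identity == rev.identity
        assert fwd.coverage == rev.coverage
        assert fwd.score == rev.score
        assert {fwd.strand, rev.strand} == {"+", "-"}


def make_hit(identity, coverage, qlen=100, ref_start=0):
    cols = 100
    return mp.AlignmentHit(
        query_id="q",
        reference_id="r",
        strand="+",
        query_start=0,
        query_end=int(round(coverage * qlen)),
        ref_start=ref_start,
        ref_end=ref_start + cols,
        score=int(100 * identity),
        matches=int(round(identity * cols)),
        aligned_columns=cols,
        query_length=qlen,
    )


class TestClassifyBes:
    def test_no_hits_unmapped(self):
        assert mp.classify_bes([], query_id="q").classification == "unmapped"

    def test_high_identity_mid_coverage_is_ambiguous(self):
        res = mp.classify_bes([make_hit(0.85, 0.50)])
        assert res.classification == "ambiguous"

    def test_high_identity_low_coverage_is_unmapped(self):
        # identity passes but coverage < 30%: the defining unmapped rule wins
        assert mp.classify_bes([make_hit(0.95, 0.20)]).classification == "unmapped"

    @pytest.mark.parametrize("identity", [0.5, 0.79, 0.80, 0.95])
    @pytest.mark.parametrize("coverage", [0.10, 0.29, 0.30, 0.50, 0.69, 0.70, 0.90])
    def test_truth_table(self, identity, coverage):
        # brute-force enumeration of the rule over the threshold grid
        if identity >= 0.80 and coverage >= 0.70:
            expected = "mapped"
        elif identity >= 0.80 and coverage >= 0.30:
            expected = "ambiguous"
        else:
            expected = "unmapped"
        assert mp.classify_bes([make_hit(identity, coverage)]).classification == expected

    def test_partition_invariant(self, rng):
        results = []
        for _ in range(200):
            nh = int(rng.integers(0, 3))
            hits = [
                make_hit(float(rng.uniform(0.5, 1.0)), float(rng.uniform(0.05, 1.0)))
                for _ in range(nh)
            ]
            results.append(mp.classify_bes(hits, query_id="q"))
        counts = {c: sum(r.classification == c for r in results) for c in ("mapped", "ambiguous", "unmapped")}
        assert sum(counts.values()) == 200

    def test_monotone_in_thresholds(self, rng):
        hit_sets = [
            [make_hit(float(rng.uniform(0.7, 1.0)), float(rng.uniform(0.1, 1.0)))]
            for _ in range(100)
        ]
        def n_mapped(cov_hi):
            return sum(mp.classify_bes(h, cov_hi=cov_hi).classification == "mapped" for h in hit_sets)
        def n_unmapped(cov_lo):
            return sum(mp.classify_bes(h, cov_lo=cov_lo).classification == "unmapped" for h in hit_sets)
        assert n_mapped(0.8) <= n_mapped(0.6)
        assert n_unmapped(0.4) >= n_unmapped(0.2)


class TestDedupe:
    def test_equal_best_multi_locus_discarded(self):
        h1, h2 = make_hit(0.9, 0.9, ref_start=0), make_hit(0.9, 0.9, ref_start=5000)
        res = mp.classify_bes([h1, h2], query_id="q")
        assert res.n_equal_best == 2
        assert mp.dedupe_for_alignment([res]) == []

    def test_same_position_highest_identity_wins(self):
        r1 = mp.MappingResult("qa", make_hit(0.95, 0.9), "mapped", 1)
        r2 = mp.MappingResult("qb", make_hit(0.90, 0.9), "mapped", 1)
        kept = mp.dedupe_for_alignment([r1, r2])
        assert [r.query_id for r in kept] == ["qa"]

    def test_same_position_tie_breaks_lexicographic(self):
        r1 = mp.MappingResult("qb", make_hit(0.9, 0.9), "mapped", 1)
        r2 = mp.MappingResult("qa", make_hit(0.9, 0.9), "mapped", 1)
        assert [r.query_id for r in mp.dedupe_for_alignment([r1, r2])] == ["qa"]

    def test_unique_placements_unchanged(self):
        rs = [
            mp.MappingResult("q1", make_hit(0.9, 0.9, ref_start=0), "mapped", 1),
            mp.MappingResult("q2", make_hit(0.9, 0.9, ref_start=900), "mapped", 1),
        ]
        assert mp.dedupe_for_alignment(rs) == rs


@pytest.fixture(scope="module")
def flat_genome():
    return sd.build_ancestral_genome(
        sd.GenomeSpec(length=400_000, n_genes=30, target_repeat_fraction=0.0), seed=77
    )


class TestPairedIntervals:

    def test_fixed_insert_recovered_exactly(self, flat_genome):
        spec = sd.CloneSpec(
            n_clones=60, insert_mean=40_000, insert_sd=0, end_length_dist=("constant", 500), seed=3
        )
        bes = sd.sample_bes(flat_genome, spec)
        index = mp.ReferenceIndex.build(flat_genome, k=13)
        results = mp.map_queries(bes, index)
        rep = mp.paired_intervals(results)
        assert rep.n_pairs > 50
        assert np.all(rep.sizes == 40_000)

    def test_reference_deletions_stretch_intervals(self, flat_genome):
        derived, log = sd.evolve_lineage(
            flat_genome,
            sd.EvolutionSpec(
                large_deletion_count=3, large_deletion_size_dist=("constant", 10_000), seed=5
            ),
        )
        # clones from the deletion-bearing lineage, mapped on the ancestor:
        # spans bridging a deletion gain its length back on the reference
        spec = sd.CloneSpec(
            n_clones=150, insert_mean=40_000, insert_sd=0, end_length_dist=("constant", 500), seed=6
        )
        bes = sd.sample_bes(derived, spec)
        index = mp.ReferenceIndex.build(flat_genome, k=13)
        rep = mp.paired_intervals(
            mp.map_queries(bes, index), insert_sample=np.full(150, 40_000.0)
        )
        assert rep.mean > 40_000
        assert max(rep.sizes) >= 49_000
        assert rep.rank_test_p is not None

    def test_interval_matches_coordinate_oracle(self, flat_genome):
        spec = sd.CloneSpec(
            n_clones=40, insert_mean=30_000, insert_sd=3_000, end_length_dist=("constant", 400), seed=9
        )
        bes = sd.sample_bes(flat_genome, spec)
        index = mp.ReferenceIndex.build(flat_genome, k=13)
        rep = mp.paired_intervals(mp.map_queries(bes, index))
        # oracle: outer distance from the recorded source coordinates
        truth = {}
        for r in bes:
            s, e = truth.get(r.clone_id, (np.inf, -np.inf))
            truth[r.clone_id] = (min(s, r.source_start), max(e, r.source_end))
        oracle_sizes = sorted(e - s for s, e in truth.values())
        assert sorted(rep.sizes.tolist()) == oracle_sizes


class TestSelfMappingRate:
    def test_saturating_mutation_kills_mapping(self, small_genome):
        rate = mp.self_mapping_rate(small_genome, 30, ("constant", 500), 0.5, seed=2)
        assert rate < 0.05

    def test_exact_fragments_all_map(self, small_genome):
        rate = mp.self_mapping_rate(small_genome, 200, ("uniform", 300, 800), 0.0, seed=3)
        assert rate >= 0.999
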