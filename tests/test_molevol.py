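"""Nei-Gojobori, K2P, NJ and the loss-rate regression, against brute-force
pathway/topology oracles."""

import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from oryzaloss import mapping as mp
from oryzaloss import molevol as mev
from oryzaloss import seqs
from oryzaloss import synthetic_data as sd

CODON_TABLE = {}  # independent oracle table built from string translation


def _aa(codon: str) -> str:
    if not CODON_TABLE:
        from Bio.Seq import Seq

        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    CODON_TABLE[a + b + c] = str(Seq(a + b + c).translate())
    return CODON_TABLE[codon]


def ng_oracle(s1: str, s2: str):
    """Brute-force pathway-enumeration oracle for Nei-Gojobori counts."""
    stops = {"TAA", "TAG", "TGA"}
    S = 0.0
    for seq in (s1, s2):
        for i in range(0, len(seq), 3):
            cod = seq[i : i + 3]
            syn = sum(
                1
                for pos in range(3)
                for alt in "ACGT"
                if alt != cod[pos]
                and (nc := cod[:pos] + alt + cod[pos + 1 :]) not in stops
                and _aa(nc) == _aa(cod)
            )
            S += syn / 3.0
    S /= 2.0
    N = len(s1) - S
    Sd = Nd = 0.0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        diff = [p for p in range(3) if c1[p] != c2[p]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur, sdp, ndp, blocked = c1, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in stops:
                    blocked = True
                if _aa(cur) == _aa(nxt):
                    sdp += 1
                else:
                    ndp += 1
                cur = nxt
            paths.append((sdp, ndp, blocked))
        ok = [(a, b) for a, b, blk in paths if not blk] or [(a, b) for a, b, _ in paths]
        Sd += sum(a for a, _ in ok) / len(ok)
        Nd += sum(b for _, b in ok) / len(ok)
    return S, N, Sd, Nd


class TestNeiGojobori:
    def test_identical_sequences_zero(self):
        r = mev.nei_gojobori("ATGGCT", "ATGGCT")
        assert r.Sd == 0 and r.Nd == 0 and r.dS == 0 and r.dN == 0

    def test_single_codon_hand_enumeration(self):
        # TTT vs TTC: one synonymous third-position difference; each codon
        # carries 1/3 synonymous site at position 3
        r = mev.nei_gojobori("TTT", "TTC")
        assert r.Sd == 1.0 and r.Nd == 0.0
        assert r.S == pytest.approx(1 / 3)
        assert r.N == pytest.approx(3 - 1 / 3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_pathway_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        sense = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        s1 = "".join(rng.choice(sense, size=10))
        # mutate a few positions, avoiding stops
        s2 = list(s1)
        for _ in range(4):
            p = int(rng.integers(0, len(s2)))
            old = s2[p]
            for alt in rng.permutation(list("ACGT")):
                s2[p] = alt
                cod = "".join(s2[p - p % 3 : p - p % 3 + 3])
                if cod not in ("TAA", "TAG", "TGA"):
                    break
                s2[p] = old
        s2 = "".join(s2)
        r = mev.nei_gojobori(s1, s2)
        S, N, Sd, Nd = ng_oracle(s1, s2)
        assert r.S == pytest.approx(S)
        assert r.N == pytest.approx(N)
        assert r.Sd == pytest.approx(Sd)
        assert r.Nd == pytest.approx(Nd)

    def test_site_counts_sum_to_three_per_codon(self, rng):
        sense = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        s1 = "".join(rng.choice(sense, size=30))
        s2 = "".join(rng.choice(sense, size=30))
        r = mev.nei_gojobori(s1, s2)
        assert r.S + r.N == pytest.approx(3 * 30)

    def test_saturation_signalled(self):
        r = mev.nei_gojobori("TTT", "TTC")  # pS = 3 on a single codon
        with pytest.raises(mev.UndefinedDistanceError):
            _ = r.dS

    def test_stop_codon_input_rejected(self):
        with pytest.raises(ValueError):
            mev.nei_gojobori("TAAGCT", "TTAGCT")


class TestK2P:
    def test_identical_zero(self):
        assert mev.k2p_pairwise("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form(self):
        # 100 sites: 10 transitions (A<->G), 5 transversions (A<->C)
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        P, Q = 0.10, 0.05
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert mev.k2p_pairwise(s1, s2) == pytest.approx(expected)

    def test_symmetric(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = "".join(
            c if rng.random() > 0.1 else "ACGT"[("ACGT".index(c) + int(rng.integers(1, 4))) % 4]
            for c in a
        )
        assert mev.k2p_pairwise(a, b) == mev.k2p_pairwise(b, a)

    def test_saturation_signalled(self):
        with pytest.raises(mev.UndefinedDistanceError):
            mev.k2p_pairwise("A" * 10, "G" * 10)


def tree_distance(tree, a, b):
    return tree.find(a).distance(tree.find(b))


def me_oracle_5taxa(dm: DistanceMatrix):
    """Exhaustive minimum-evolution search over the 15 unrooted 5-taxon
    topologies with least-squares branch lengths."""
    taxa = list(dm.ids)
    best = None
    for middle in taxa:
        rest = [t for t in taxa if t != middle]
        a = rest[0]
        for partner_i in range(1, 4):
            pair1 = (a, rest[partner_i])
            pair2 = tuple(t for t in rest[1:] if t != rest[partner_i])
            order = [pair1[0], pair1[1], pair2[0], pair2[1], middle]
            # branches: t0..t4 pendant, x (cherry1-center), y (cherry2-center);
            # a path uses x iff it leaves cherry1 and y iff it leaves cherry2
            def pend(t):
                return order.index(t)
            rows, rhs = [], []
            for i, j in itertools.combinations(taxa, 2):
                row = [0.0] * 7
                row[pend(i)] = 1
                row[pend(j)] = 1
                side = {0: "c1", 1: "c1", 2: "c2", 3: "c2", 4: "mid"}
                si, sj = side[pend(i)], side[pend(j)]
                if si != sj:
                    if "c1" in (si, sj):
                        row[5] = 1
                    if "c2" in (si, sj):
                        row[6] = 1
                rows.append(row)
                rhs.append(dm[i, j])
            A = np.asarray(rows)
            b, *_ = np.linalg.lstsq(A, np.asarray(rhs), rcond=None)
            resid = float(np.sum((A @ b - np.asarray(rhs)) ** 2))
            score = float(np.sum(b))
            split = frozenset(pair1)
            key = (round(resid, 9), round(score, 9))
            if best is None or key < best[0]:
                best = (key, {frozenset(pair1), frozenset(pair2)})
    return best[1]


class TestNJTree:
    def make_additive(self):
        # ((A:2,B:3):1,(C:4,D:1):2,E:5) unrooted
        taxa = ["A", "B", "C", "D", "E"]
        pend = {"A": 2.0, "B": 3.0, "C": 4.0, "D": 1.0, "E": 5.0}
        x, y = 1.0, 2.0
        side = {"A": "c1", "B": "c1", "C": "c2", "D": "c2", "E": "mid"}
        m = np.zeros((5, 5))
        for i, j in itertools.combinations(range(5), 2):
            ti, tj = taxa[i], taxa[j]
            d = pend[ti] + pend[tj]
            if side[ti] != side[tj]:
                if "c1" in (side[ti], side[tj]):
                    d += x
                if "c2" in (side[ti], side[tj]):
                    d += y
            m[i, j] = m[j, i] = d
        return DistanceMatrix(m, ids=taxa)

    def test_additive_matrix_recovered_exactly(self):
        dm = self.make_additive()
        tree, _ = mev.nj_tree(dm)
        for i, j in itertools.combinations(dm.ids, 2):
            assert tree_distance(tree, i, j) == pytest.approx(dm[i, j])

    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix(np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float), ids=list("ABC"))
        tree, _ = mev.nj_tree(dm)
        # three-point: tA=(dAB+dAC-dBC)/2=3, tB=2, tC=6
        assert tree_distance(tree, "A", "B") == pytest.approx(5)
        assert tree_distance(tree, "A", "C") == pytest.approx(9)
        assert tree_distance(tree, "B", "C") == pytest.approx(8)

    def test_topology_matches_minimum_evolution_oracle(self):
        dm = self.make_additive()
        tree, _ = mev.nj_tree(dm)
        full = frozenset(dm.ids)
        splits = mev._bipartitions(tree, full)
        oracle = {p if "A" not in p else full - p for p in me_oracle_5taxa(dm)}
        assert splits == oracle

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(5):
            pend = rng.uniform(0.5, 4.0, size=5)
            x, y = rng.uniform(0.5, 2.0, size=2)
            taxa = list("ABCDE")
            side = {"A": "c1", "B": "c1", "C": "c2", "D": "c2", "E": "mid"}
            m = np.zeros((5, 5))
            for i, j in itertools.combinations(range(5), 2):
                d = pend[i] + pend[j]
                si, sj = side[taxa[i]], side[taxa[j]]
                if si != sj:
                    d += x if "c1" in (si, sj) else 0
                    d += y if "c2" in (si, sj) else 0
                m[i, j] = m[j, i] = d
            tree, _ = mev.nj_tree(DistanceMatrix(m, ids=taxa))
            cherries = {
                frozenset(t.name for t in n.tips())
                for n in tree.non_tips(include_self=False)
            }
            assert frozenset("AB") in cherries or frozenset("CDE") in cherries

    def test_too_few_taxa_raises(self):
        with pytest.raises(ValueError):
            mev.nj_tree(DistanceMatrix(np.zeros((2, 2)), ids=["A", "B"]))

    def test_bootstrap_supports_bounded_and_saturate(self, rng):
        # strongly structured alignment: clades differ at every site
        n = 300
        block = "".join(rng.choice(list("ACGT"), size=n))
        def perturb(s, rate, seed):
            r2 = np.random.default_rng(seed)
            out = [
                c if r2.random() > rate else "ACGT"[("ACGT".index(c) + 1) % 4] for c in s
            ]
            return "".join(out)
        # C and D share a long internal branch, so their split is certain
        c = perturb(block, 0.20, 2)
        aln = {
            "A": block,
            "B": perturb(block, 0.02, 1),
            "C": c,
            "D": perturb(c, 0.02, 3),
        }
        dm = mev.distance_matrix(aln)
        tree, supports = mev.nj_tree(dm, aln, bootstrap=50, seed=9)
        assert supports
        for v in supports.values():
            assert 0 <= v <= 100
        assert max(supports.values()) == 100


class TestLossRateRegression:
    def test_exact_line_no_flag(self):
        pts = [(1.0, 10.0), (2.0, 20.0), (3.0, 30.0)]
        rep = mev.loss_rate_regression(pts, near_origin_points=[(0.5, 5.0)])
        assert rep.slope_origin == pytest.approx(10.0)
        assert not rep.accelerated

    def test_planted_acceleration_flagged(self):
        pts = [(1.0, 10.0), (2.0, 21.0), (3.0, 29.0)]
        rep = mev.loss_rate_regression(pts, near_origin_points=[(0.2, 15.0)])
        assert rep.accelerated

    def test_normal_equations_oracle(self, rng):
        x = rng.uniform(0.5, 5, size=6)
        y = 3.3 * x + rng.normal(0, 0.3, size=6)
        rep = mev.loss_rate_regression(list(zip(x, y)))
        assert rep.slope_origin == pytest.approx(float(np.sum(x * y) / np.sum(x * x)))
        sf, intf = np.polyfit(x, y, 1)
        assert rep.slope_free == pytest.approx(float(sf))
        assert rep.intercept_free == pytest.approx(float(intf))

    def test_zero_distances_raise(self):
        with pytest.raises(ValueError):
            mev.loss_rate_regression([(0.0, 1.0), (0.0, 2.0)])


class TestDivergenceTime:
    def test_published_timing(self):
        t = mev.divergence_time(4.3e-3, 6.5e-9)
        assert t == pytest.approx(330_769, abs=1)

    def test_zero_distance(self):
        assert mev.divergence_time(0.0, 1e-9) == 0.0

    def test_linear_in_distance(self):
        assert mev.divergence_time(2e-3, 1e-9) * 2 == mev.divergence_time(4e-3, 1e-9)

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            mev.divergence_time(1e-3, 0.0)


def full_coverage_hit(taxon_codes, ref_len, identity=1.0):
    return mp.AlignmentHit(
        query_id="b",
        reference_id="ref",
        strand="+",
        query_start=0,
        query_end=ref_len,
        ref_start=0,
        ref_end=ref_len,
        score=ref_len,
        matches=int(identity * ref_len),
        aligned_columns=ref_len,
        query_length=ref_len,
        pairs=(np.arange(ref_len), taxon_codes.copy()),
    )


class TestExtractSharedCodons:
    def make_reference(self):
        rng = np.random.default_rng(31)
        bg = rng.integers(0, 4, size=600).astype(np.uint8)
        gene1 = sd._random_gene(90, rng)
        gene2 = sd._random_gene(60, rng)
        codes = np.concatenate((bg[:50], gene1, bg[50:100], gene2, bg[100:150]))
        genes = [
            sd.Gene("g1", 50, 50 + gene1.size),
            sd.Gene("g2", 50 + gene1.size + 50, 50 + gene1.size + 50 + gene2.size),
        ]
        return sd.AnnotatedGenome("ref", codes, genes, [])

    def test_identical_taxa_give_reference_codons(self):
        ref = self.make_reference()
        placements = {
            "t1": [full_coverage_hit(ref.codes, ref.length)],
            "t2": [full_coverage_hit(ref.codes, ref.length)],
        }
        aln = mev.extract_shared_codons(placements, ref)
        expected = "".join(
            seqs.decode(ref.codes[g.start : g.end]) for g in ref.genes
        )
        assert aln.sequences["ref"] == expected
        assert aln.sequences["t1"] == expected

    def test_all_columns_covered_in_all_taxa(self):
        ref = self.make_reference()
        partial = ref.codes.copy()
        # taxon covers only the first 300 bases
        hit = mp.AlignmentHit(
            "b", "ref", "+", 0, 300, 0, 300, 300, 300, 300, 300,
            pairs=(np.arange(300), partial[:300].copy()),
        )
        placements = {"t1": [hit], "t2": [full_coverage_hit(ref.codes, ref.length)]}
        aln = mev.extract_shared_codons(placements, ref)
        for _gene, pos in aln.columns:
            assert pos + 3 <= 300  # recount oracle: within everyone's coverage

    def test_internal_stop_excludes_whole_gene(self):
        ref = self.make_reference()
        mutant = ref.codes.copy()
        g1 = ref.genes[0]
        # force TAA at the second codon of gene 1
        mutant[g1.start + 3 : g1.start + 6] = seqs.encode("TAA")
        placements = {
            "t1": [full_coverage_hit(mutant, ref.length)],
            "t2": [full_coverage_hit(ref.codes, ref.length)],
        }
        aln = mev.extract_shared_codons(placements, ref)
        genes_in_alignment = {g for g, _ in aln.columns}
        assert genes_in_alignment == {"g2"}

    def test_no_shared_codons_raises(self):
        ref = self.make_reference()
        hit = mp.AlignmentHit(
            "b", "ref", "+", 0, 10, 0, 10, 10, 10, 10, 10,
            pairs=(np.arange(10), ref.codes[:10].copy()),
        )
        with pytest.raises(ValueError):
            mev.extract_shared_codons({"t1": [hit]}, ref)
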