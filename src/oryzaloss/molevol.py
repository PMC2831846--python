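"""Molecular-evolution analyses on codons shared across the mapped taxa.

Covers shared-codon extraction from per-species placements, Nei-Gojobori
synonymous/nonsynonymous distances (pathway counting with Jukes-Cantor
correction), Kimura two-parameter distances on third codon positions,
neighbour-joining trees with site-resampling bootstrap, the lost-genes vs
synonymous-distance regression used to detect recent acceleration of gene
loss, and divergence timing T = d_S / (2 mu).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from . import seqs
from .synthetic_data import AnnotatedGenome

# Standard nuclear genetic code over base codes A=0, C=1, G=2, T=3.
_BASES = "ACGT"
_TABLE = {}


def _build_code() -> dict[tuple[int, int, int], str]:
    if not _TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        fwd = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            fwd[stop] = "*"
        for codon, aa in fwd.items():
            key = tuple(_BASES.index(c) for c in codon)
            _TABLE[key] = aa
    return _TABLE


def translate_codon(codon: tuple[int, int, int]) -> str:
    return _build_code()[codon]


STOP_CODONS = frozenset(
    tuple("ACGT".index(c) for c in codon) for codon in ("TAA", "TAG", "TGA")
)


class UndefinedDistanceError(ValueError):
    """Raised when a distance correction leaves its domain (saturation)."""


@dataclass
class CodonAlignment:
    """Concatenated in-frame codon columns shared by all taxa."""

    taxa: list[str]
    sequences: dict[str, str]
    columns: list[tuple[str, int]] = field(default_factory=list)  # (gene id, ref pos of codon)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3 if self.sequences else 0

    def third_positions(self) -> dict[str, str]:
        return {t: s[2::3] for t, s in self.sequences.items()}

    def write_fasta(self, path) -> None:
        seqs.write_fasta(path, self.sequences.items())

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            n = len(self.taxa)
            ln = len(self.sequences[self.taxa[0]]) if self.taxa else 0
            fh.write(f" {n} {ln}\n")
            for t in self.taxa:
                fh.write(f"{t}  {self.sequences[t]}\n")


def extract_shared_codons(
    placements: dict[str, Sequence],
    reference: AnnotatedGenome,
    ref_taxon: str | None = None,
) -> CodonAlignment:
    """Codon columns covered by every taxon's deduplicated placements.

    ``placements`` maps taxon name to alignment hits that carry per-column
    (reference position, query base) pairs.  The reference itself enters the
    alignment as one taxon.  Per-gene, codons fully covered in all taxa are
    kept; a gene is dropped entirely when any taxon shows an internal stop
    codon among its retained codons.
    """
    ref_taxon = ref_taxon or reference.name
    L = reference.length
    pile: dict[str, np.ndarray] = {}
    ident: dict[str, np.ndarray] = {}
    for taxon, hits in placements.items():
        arr = np.full(L, -1, dtype=np.int8)
        best = np.full(L, -1.0)
        for h in hits:
            if h.pairs is None:
                raise ValueError("placements must be aligned with keep_pairs=True")
            rpos, qb = h.pairs
            take = h.identity >= best[rpos]
            arr[rpos[take]] = qb[take]
            best[rpos[take]] = h.identity
        pile[taxon] = arr
        ident[taxon] = best
    taxa = [ref_taxon] + sorted(placements)
    out: dict[str, list[str]] = {t: [] for t in taxa}
    columns: list[tuple[str, int]] = []
    for gene in reference.genes:
        n_cod = (gene.end - gene.start) // 3
        gene_cols: list[int] = []
        for c in range(n_cod):
            p = gene.start + 3 * c
            if all(int(pile[t][p + o]) >= 0 for t in placements for o in range(3)):
                gene_cols.append(p)
        if not gene_cols:
            continue
        gene_seqs: dict[str, str] = {}
        stop_found = False
        for t in taxa:
            codons = []
            for p in gene_cols:
                if t == ref_taxon:
                    tri = tuple(int(x) for x in reference.codes[p : p + 3])
                else:
                    tri = tuple(int(pile[t][p + o]) for o in range(3))
                if max(tri) > 3:
                    stop_found = True  # ambiguity excludes the column's gene
                    break
                if tri in STOP_CODONS:
                    stop_found = True
                    break
                codons.append("".join(_BASES[x] for x in tri))
            if stop_found:
                break
            gene_seqs[t] = "".join(codons)
        if stop_found:
            continue
        for t in taxa:
            out[t].append(gene_seqs[t])
        columns.extend((gene.gene_id, p) for p in gene_cols)
    if not columns:
        raise ValueError("no codons shared by all taxa")
    return CodonAlignment(taxa, {t: "".join(v) for t, v in out.items()}, columns)


# ---------------------------------------------------------------------------
# Nei-Gojobori


def _syn_fraction(codon: tuple[int, int, int]) -> float:
    """Synonymous fraction of the nine single-base changes of a codon.

    Changes producing stop codons count as nonsynonymous, so the synonymous
    plus nonsynonymous site totals are exactly 3 per codon.
    """
    aa = translate_codon(codon)
    syn = 0
    for pos in range(3):
        for alt in range(4):
            if alt == codon[pos]:
                continue
            new = list(codon)
            new[pos] = alt
            if translate_codon(tuple(new)) == aa and tuple(new) not in STOP_CODONS:
                syn += 1
    return syn / 3.0


def _codon_path_counts(c1: tuple, c2: tuple) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all minimal
    substitution pathways between two codons (stop-containing pathways are
    excluded; when every pathway is blocked, all are used)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = list(c1)
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = list(cur)
            nxt[pos] = c2[pos]
            if tuple(nxt) in STOP_CODONS:
                blocked = True
            if translate_codon(tuple(cur)) == translate_codon(tuple(nxt)):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [(s, n) for s, n, b in paths if not b] or [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise UndefinedDistanceError(f"proportion {p:.4f} >= 3/4; distance undefined")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class NGResult:
    S: float
    N: float
    Sd: float
    Nd: float

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N else 0.0

    @property
    def dS(self) -> float:
        return _jukes_cantor(self.pS)

    @property
    def dN(self) -> float:
        return _jukes_cantor(self.pN)


def _codons_of(seq: str) -> list[tuple[int, int, int]]:
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    up = seq.upper()
    out = []
    for i in range(0, len(up), 3):
        tri = up[i : i + 3]
        if any(c not in _BASES for c in tri):
            raise ValueError(f"ambiguous codon {tri!r}")
        out.append(tuple(_BASES.index(c) for c in tri))
    return out


def nei_gojobori(seq1: str, seq2: str) -> NGResult:
    """Pathway-counting synonymous/nonsynonymous estimation for one pair of
    equal-length in-frame coding sequences (no gaps, no stops)."""
    c1, c2 = _codons_of(seq1), _codons_of(seq2)
    if len(c1) != len(c2):
        raise ValueError("sequences differ in length")
    for cs in (c1, c2):
        for c in cs:
            if c in STOP_CODONS:
                raise ValueError("input contains a stop codon")
    S1 = sum(_syn_fraction(c) for c in c1)
    S2 = sum(_syn_fraction(c) for c in c2)
    S = (S1 + S2) / 2.0
    N = 3.0 * len(c1) - S
    Sd = Nd = 0.0
    for a, b in zip(c1, c2):
        s, n = _codon_path_counts(a, b)
        Sd += s
        Nd += n
    return NGResult(S=S, N=N, Sd=Sd, Nd=Nd)


# ---------------------------------------------------------------------------
# Kimura two-parameter


def k2p_pairwise(s1: str, s2: str) -> float:
    """K2P distance from transition/transversion proportions."""
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    a1 = seqs.encode(s1)
    a2 = seqs.encode(s2)
    ok = (a1 < 4) & (a2 < 4)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    diff = ok & (a1 != a2)
    # transitions are A<->G and C<->T: codes differ by an even amount
    transition = diff & (((a1.astype(np.int16) - a2) % 2) == 0)
    P = int(transition.sum()) / n
    Q = int((diff & ~transition).sum()) / n
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise UndefinedDistanceError("K2P correction out of domain (saturation)")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def distance_matrix(
    sequences: dict[str, str], dist_fn: Callable[[str, str], float] = k2p_pairwise
) -> DistanceMatrix:
    taxa = list(sequences)
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist_fn(sequences[taxa[i]], sequences[taxa[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=taxa)


# ---------------------------------------------------------------------------
# Neighbour joining with bootstrap


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits, each normalised to the side without the first
    (alphabetical) taxon so orientations compare equal."""
    anchor = min(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(taxa - clade) < 2:
            continue
        if anchor in clade:
            clade = frozenset(taxa - clade)
        parts.add(clade)
    return parts


def nj_tree(
    dm: DistanceMatrix,
    alignment: dict[str, str] | None = None,
    bootstrap: int = 0,
    seed: int = 0,
    dist_fn: Callable[[str, str], float] = k2p_pairwise,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Saitou-Nei neighbour joining, optional site-resampling bootstrap.

    Returns the unrooted tree and a dict mapping each internal split to its
    bootstrap support in percent (empty when bootstrap == 0).  Supports are
    also written onto the internal node names of the returned tree.
    """
    if len(dm.ids) < 3:
        raise ValueError("need at least 3 taxa")
    if not np.isfinite(dm.data).all():
        raise ValueError("degenerate distance matrix")
    tree = _skbio_nj(dm)
    supports: dict[frozenset[str], float] = {}
    if bootstrap > 0:
        if alignment is None:
            raise ValueError("bootstrap requires the character alignment")
        taxa = frozenset(dm.ids)
        counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(tree, taxa)}
        rng = np.random.default_rng(seed)
        ln = len(next(iter(alignment.values())))
        arrs = {t: np.frombuffer(s.encode(), dtype=np.uint8) for t, s in alignment.items()}
        n_ok = 0
        for _ in range(bootstrap):
            idx = rng.integers(0, ln, size=ln)
            resampled = {t: a[idx].tobytes().decode() for t, a in arrs.items()}
            try:
                bdm = distance_matrix(resampled, dist_fn)
                bparts = _bipartitions(_skbio_nj(bdm), taxa)
            except (UndefinedDistanceError, ValueError):
                continue  # saturated replicate carries no topological signal
            n_ok += 1
            for bp in counts:
                if bp in bparts:
                    counts[bp] += 1
        supports = {bp: 100.0 * c / max(n_ok, 1) for bp, c in counts.items()}
        for node in tree.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            key = clade if clade in supports else frozenset(taxa - clade)
            if key in supports:
                node.name = str(int(round(supports[key])))
    return tree, supports


# ---------------------------------------------------------------------------
# Loss-rate regression and timing


@dataclass
class RegressionReport:
    slope_origin: float
    slope_free: float
    intercept_free: float
    rms_residual: float
    residuals: list[float]
    near_origin_residuals: list[float]
    accelerated: bool


def loss_rate_regression(
    points: Sequence[tuple[float, float]],
    near_origin_points: Sequence[tuple[float, float]] = (),
) -> RegressionReport:
    """Fit lost-gene counts against synonymous distance.

    The null model (constant loss rate) is a least-squares line through the
    origin over ``points``; ``near_origin_points`` (the recently diverged
    cultivar pair) are held out and flagged as accelerated when they sit
    above the line by more than twice the fitted residual spread.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all distances are zero")
    slope = float(np.sum(x * y) / sxx)
    resid = (y - slope * x).tolist()
    rms = float(np.sqrt(np.mean(np.square(resid))))
    # free-intercept fit reported for comparison
    A = np.vstack([x, np.ones_like(x)]).T
    (sf, intf), *_ = np.linalg.lstsq(A, y, rcond=None)
    scale = max(abs(float(v)) for v in y) or 1.0
    thresh = max(2 * rms, 1e-6 * scale)
    near_res = [float(ny - slope * nx) for nx, ny in near_origin_points]
    accelerated = any(r > thresh for r in near_res)
    return RegressionReport(
        slope_origin=slope,
        slope_free=float(sf),
        intercept_free=float(intf),
        rms_residual=rms,
        residuals=[float(r) for r in resid],
        near_origin_residuals=near_res,
        accelerated=accelerated,
    )


def divergence_time(d_s: float, mu: float) -> float:
    """Years since divergence for a pairwise synonymous distance, assuming a
    symmetric pair of lineages: T = d_S / (2 mu)."""
    if mu <= 0:
        raise ValueError("substitution rate must be positive")
    return d_s / (2.0 * mu)
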