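"""Seed-and-extend local alignment of end sequences to a reference.

The mapper mirrors a BLASTN-style workflow at desk scale: exact k-mer seeds
(k=13 by default) taken from unmasked query bases, diagonal voting to pick
candidate loci, and an affine-gap local dynamic-programming extension
(match +1, mismatch -2, gap open -5, gap extend -2) over a window around
each candidate diagonal.  On a window the full Gotoh recurrence is solved,
so when the window spans the whole reference the best hit score is exactly
the Smith-Waterman optimum under the same scoring.

Hits feed the three-way classification used throughout the pipeline:
mapped (identity >= 0.80 and coverage >= 0.70), ambiguous (identity >= 0.80
and coverage >= 0.30) and unmapped (everything else, including no hit).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from . import seqs
from .repeatmask import MaskedSequence
from .synthetic_data import AnnotatedGenome, BESRecord, simulate_bes_from_genome


@dataclass(frozen=True)
class AlignParams:
    k: int = 13
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    band_pad: int = 48
    diag_bin: int = 24
    max_candidates: int = 8
    max_kmer_occ: int = 256  # over-represented seeds are subsampled to this many loci


@dataclass
class AlignmentHit:
    query_id: str
    reference_id: str
    strand: str
    query_start: int  # original query orientation, 0-based half-open
    query_end: int
    ref_start: int
    ref_end: int
    score: int
    matches: int
    aligned_columns: int
    query_length: int
    pairs: tuple[np.ndarray, np.ndarray] | None = None  # (ref positions, query base codes)

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0

    @property
    def coverage(self) -> float:
        return (self.query_end - self.query_start) / self.query_length if self.query_length else 0.0

    @property
    def mismatches(self) -> int:
        return self.aligned_columns - self.matches


@dataclass
class MappingResult:
    query_id: str
    best_hit: AlignmentHit | None
    classification: str  # mapped | ambiguous | unmapped
    n_equal_best: int = 1
    source: object = None


@njit(cache=True)
def _gotoh_local(q, r, match, mismatch, gap_open, gap_ext, lo_d, hi_d):  # pragma: no cover - numba
    """Affine-gap local DP restricted to the diagonal band lo_d <= j-i <= hi_d.

    Pass lo_d <= -n and hi_d >= m for the full Smith-Waterman matrix; cells
    outside the band keep H=0 / E,F=-inf so the recurrence stays exact for
    any path inside the band.
    """
    n = q.shape[0]
    m = r.shape[0]
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    ptrH = np.zeros((n + 1, m + 1), np.uint8)
    ptrE = np.zeros((n + 1, m + 1), np.uint8)
    ptrF = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qc = q[i - 1]
        jlo = i + lo_d
        if jlo < 1:
            jlo = 1
        jhi = i + hi_d
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            eo = H[i, j - 1] + gap_open + gap_ext
            ee = E[i, j - 1] + gap_ext
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
            fo = H[i - 1, j] + gap_open + gap_ext
            fe = F[i - 1, j] + gap_ext
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
            rc = r[j - 1]
            s = match if (qc == rc and qc < 4) else mismatch
            d = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    qp = np.empty(n + m, np.int32)
    rp = np.empty(n + m, np.int32)
    npair = 0
    matches = 0
    cols = 0
    i = bi
    j = bj
    while i > 0 and j > 0 and ptrH[i, j] != 0:
        p = ptrH[i, j]
        if p == 1:
            qp[npair] = i - 1
            rp[npair] = j - 1
            npair += 1
            if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                matches += 1
            cols += 1
            i -= 1
            j -= 1
        elif p == 2:
            while True:
                opened = ptrE[i, j]
                cols += 1
                j -= 1
                if opened == 1:
                    break
        else:
            while True:
                opened = ptrF[i, j]
                cols += 1
                i -= 1
                if opened == 1:
                    break
    return best, i, bi, j, bj, matches, cols, qp[:npair][::-1].copy(), rp[:npair][::-1].copy()


class ReferenceIndex:
    """Sorted k-mer index over one or more reference sequences.

    Sequences are concatenated with a sentinel so alignment windows never
    cross a boundary.  Seeds may optionally be restricted to reference
    positions whose whole k-mer window is unmasked (soft-mask semantics).
    """

    def __init__(self, names, offsets, lengths, concat, svals, spos, k):
        self.names = names
        self.offsets = offsets
        self.lengths = lengths
        self.concat = concat
        self.svals = svals
        self.spos = spos
        self.k = k

    @classmethod
    def build(
        cls,
        references: Sequence[tuple[str, np.ndarray]] | Sequence[MaskedSequence] | AnnotatedGenome,
        k: int = 13,
        seed_unmasked_only: bool = False,
    ) -> "ReferenceIndex":
        if isinstance(references, AnnotatedGenome):
            references = [(references.name, references.codes)]
        names, parts, masks = [], [], []
        for ref in references:
            if isinstance(ref, MaskedSequence):
                names.append(ref.seq_id)
                parts.append(ref.codes)
                masks.append(ref.mask)
            else:
                name, codes = ref
                names.append(name)
                parts.append(np.asarray(codes, dtype=np.uint8))
                masks.append(np.zeros(len(codes), bool))
        sep = np.full(1, 4, dtype=np.uint8)
        concat_parts, mask_parts, offsets = [], [], []
        pos = 0
        for codes, m in zip(parts, masks):
            offsets.append(pos)
            concat_parts.append(codes)
            mask_parts.append(m)
            concat_parts.append(sep)
            mask_parts.append(np.zeros(1, bool))
            pos += codes.size + 1
        concat = np.concatenate(concat_parts) if concat_parts else np.empty(0, np.uint8)
        cmask = np.concatenate(mask_parts) if mask_parts else np.empty(0, bool)
        vals, ok = seqs.kmer_values(concat, k)
        if seed_unmasked_only:
            bad = cmask.astype(np.int32)
            cs = np.concatenate(([0], np.cumsum(bad)))
            ok = ok & ((cs[k:] - cs[:-k]) == 0)
        positions = np.flatnonzero(ok)
        v = vals[positions]
        order = np.argsort(v, kind="stable")
        return cls(
            names,
            np.asarray(offsets, dtype=np.int64),
            np.asarray([p.size for p in parts], dtype=np.int64),
            concat,
            v[order],
            positions[order],
            k,
        )

    def locate(self, concat_pos: int) -> tuple[int, int]:
        """(sequence index, local position) of a concatenated coordinate."""
        si = int(np.searchsorted(self.offsets, concat_pos, side="right") - 1)
        return si, int(concat_pos - self.offsets[si])


def _query_kmers(codes: np.ndarray, mask: np.ndarray | None, k: int) -> tuple[np.ndarray, np.ndarray]:
    vals, ok = seqs.kmer_values(codes, k)
    if mask is not None and mask.any():
        bad = mask.astype(np.int32)
        cs = np.concatenate(([0], np.cumsum(bad)))
        ok = ok & ((cs[k:] - cs[:-k]) == 0)
    qpos = np.flatnonzero(ok)
    return vals[qpos], qpos


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenate arange(lo[i], hi[i]) without a Python loop."""
    c = hi - lo
    total = int(c.sum())
    if total == 0:
        return np.empty(0, np.int64)
    step = np.ones(total, np.int64)
    offs = np.cumsum(c) - c
    # first element of each range jumps from the previous range's last value
    step[offs[0]] = lo[0]
    step[offs[1:]] = lo[1:] - (lo[:-1] + c[:-1]) + 1
    return np.cumsum(step)


def align_local(
    query: MaskedSequence | BESRecord | np.ndarray,
    index: ReferenceIndex,
    params: AlignParams = AlignParams(),
    use_query_mask: bool = True,
    keep_pairs: bool = False,
) -> list[AlignmentHit]:
    """All candidate local alignments of one query, best first."""
    if isinstance(query, MaskedSequence):
        qid, qcodes, qmask = query.seq_id, query.codes, query.mask
    elif isinstance(query, BESRecord):
        qid, qcodes, qmask = query.record_id, query.codes, None
    else:
        qid, qcodes, qmask = "query", np.asarray(query, dtype=np.uint8), None
    n = qcodes.size
    if n < params.k:
        return []
    # gather diagonal-vote candidates over both strands, then extend in vote
    # order; stop once a confident hit exists and the remaining candidates
    # have clearly fewer seed votes (equal-best repeat copies keep similar
    # vote counts, so multi-mapping detection survives the early stop)
    candidates: list[tuple[int, str, int, int]] = []  # votes, strand, dmin, dmax
    per_strand: dict[str, np.ndarray] = {}
    for strand in "+-":
        qc = qcodes if strand == "+" else seqs.revcomp(qcodes)
        per_strand[strand] = qc
        qm = None
        if use_query_mask and qmask is not None:
            qm = qmask if strand == "+" else qmask[::-1]
        vq, qpos = _query_kmers(qc, qm, params.k)
        if vq.size == 0:
            continue
        lo = np.searchsorted(index.svals, vq, side="left")
        hi = np.searchsorted(index.svals, vq, side="right")
        cnt = hi - lo
        sel = cnt > 0
        if not sel.any():
            continue
        # subsample over-represented seeds instead of dropping them, so reads
        # lying entirely inside a high-copy repeat still seed somewhere
        hi_cap = np.minimum(hi, lo + params.max_kmer_occ)
        flat = _expand_ranges(lo[sel], hi_cap[sel])
        rp = index.spos[flat]
        qrep = np.repeat(qpos[sel], (hi_cap - lo)[sel])
        diag = rp - qrep
        bins = diag // params.diag_bin
        ubins, counts = np.unique(bins, return_counts=True)
        order = np.argsort(counts)[::-1]
        chosen: list[int] = []
        for bi_ in order[: params.max_candidates * 4]:
            b = int(ubins[bi_])
            if any(abs(b - c) <= 1 for c in chosen):
                continue
            chosen.append(b)
            if len(chosen) >= params.max_candidates:
                break
        for b in chosen:
            in_bin = np.abs(bins - b) <= 1
            dvals = diag[in_bin]
            candidates.append((int(in_bin.sum()), strand, int(dvals.min()), int(dvals.max())))
    candidates.sort(key=lambda c: -c[0])

    hits: list[AlignmentHit] = []
    best_votes_hit = 0  # votes of the candidate that yielded a confident hit
    for votes, strand, dmin, dmax in candidates:
        if best_votes_hit and votes < 0.5 * best_votes_hit:
            break
        qc = per_strand[strand]
        mid = min(max(0, (dmin + dmax) // 2 + n // 2), index.concat.size - 1)
        si, _ = index.locate(mid)
        soff = int(index.offsets[si])
        send = soff + int(index.lengths[si])
        ws = max(soff, dmin - params.band_pad)
        we = min(send, dmax + n + params.band_pad)
        if we <= ws:
            continue
        window = index.concat[ws:we]
        score, qs, qe, rs, re, matches, cols, qpr, rpr = _gotoh_local(
            qc,
            window,
            params.match,
            params.mismatch,
            params.gap_open,
            params.gap_extend,
            dmin - params.band_pad - ws,
            dmax + params.band_pad - ws,
        )
        if score <= 0 or cols == 0:
            continue
        if strand == "+":
            oqs, oqe = qs, qe
        else:
            oqs, oqe = n - qe, n - qs
        pairs = None
        if keep_pairs:
            pairs = ((rpr + ws - soff).astype(np.int64), qc[qpr].copy())
        h = AlignmentHit(
            query_id=qid,
            reference_id=index.names[si],
            strand=strand,
            query_start=int(oqs),
            query_end=int(oqe),
            ref_start=int(rs + ws - soff),
            ref_end=int(re + ws - soff),
            score=int(score),
            matches=int(matches),
            aligned_columns=int(cols),
            query_length=int(n),
            pairs=pairs,
        )
        hits.append(h)
        if not best_votes_hit and h.identity >= 0.8 and h.coverage >= 0.7:
            best_votes_hit = votes
    # collapse duplicate discoveries of the same locus, keep best scoring
    hits.sort(key=lambda h: (-h.score, -h.identity, h.reference_id, h.ref_start, h.strand))
    kept: list[AlignmentHit] = []
    for h in hits:
        dup = False
        for g in kept:
            if g.reference_id == h.reference_id and g.strand == h.strand:
                ov = seqs.overlap_len((g.ref_start, g.ref_end), (h.ref_start, h.ref_end))
                if ov > 0.5 * min(g.ref_end - g.ref_start, h.ref_end - h.ref_start):
                    dup = True
                    break
        if not dup:
            kept.append(h)
    return kept


def classify_bes(
    hits: Sequence[AlignmentHit],
    id_hi: float = 0.80,
    cov_hi: float = 0.70,
    cov_lo: float = 0.30,
    query_id: str | None = None,
) -> MappingResult:
    """Three-way classification from a hit list (possibly empty).

    mapped iff some hit reaches both identity >= id_hi and coverage >=
    cov_hi; otherwise ambiguous iff some hit reaches identity >= id_hi and
    coverage >= cov_lo; otherwise unmapped.  A hit passing identity but with
    coverage < cov_lo is therefore unmapped, matching the defining rule
    "identity < 80% or coverage < 30%".
    """
    qid = query_id or (hits[0].query_id if hits else "?")
    if not hits:
        return MappingResult(qid, None, "unmapped", 0)
    mapped = [h for h in hits if h.identity >= id_hi and h.coverage >= cov_hi]
    if mapped:
        best = max(mapped, key=lambda h: h.score)
        cls = "mapped"
    else:
        amb = [h for h in hits if h.identity >= id_hi and h.coverage >= cov_lo]
        if amb:
            best = max(amb, key=lambda h: h.score)
            cls = "ambiguous"
        else:
            best = max(hits, key=lambda h: h.score)
            cls = "unmapped"
    n_eq = sum(
        1 for h in hits if h.identity == best.identity and h.coverage == best.coverage
    )
    return MappingResult(qid, best, cls, n_eq)


def map_queries(
    queries: Iterable[MaskedSequence | BESRecord],
    index: ReferenceIndex,
    params: AlignParams = AlignParams(),
    id_hi: float = 0.80,
    cov_hi: float = 0.70,
    cov_lo: float = 0.30,
    use_query_mask: bool = True,
    keep_pairs: bool = False,
) -> list[MappingResult]:
    out = []
    for q in queries:
        hits = align_local(q, index, params, use_query_mask=use_query_mask, keep_pairs=keep_pairs)
        res = classify_bes(
            hits,
            id_hi,
            cov_hi,
            cov_lo,
            query_id=q.seq_id if isinstance(q, MaskedSequence) else q.record_id,
        )
        res.source = q
        out.append(res)
    return out


def dedupe_for_alignment(results: Sequence[MappingResult]) -> list[MappingResult]:
    """Placement dedup before the molecular-evolution stage.

    Queries with several equal-best placements (same identity and coverage)
    are discarded; when several queries occupy the same reference position,
    the highest-identity one wins, ties broken by query id.
    """
    placed = [r for r in results if r.best_hit is not None and r.n_equal_best <= 1]
    placed.sort(key=lambda r: (r.best_hit.reference_id, r.best_hit.ref_start, r.query_id))
    kept: list[MappingResult] = []
    for r in placed:
        if kept:
            g = kept[-1]
            same = (
                g.best_hit.reference_id == r.best_hit.reference_id
                and seqs.overlap_len(
                    (g.best_hit.ref_start, g.best_hit.ref_end),
                    (r.best_hit.ref_start, r.best_hit.ref_end),
                )
                > 0
            )
            if same:
                better = (
                    (r.best_hit.identity, g.query_id) > (g.best_hit.identity, r.query_id)
                )
                if better:
                    kept[-1] = r
                continue
        kept.append(r)
    return kept


@dataclass
class PairedIntervalReport:
    sizes: np.ndarray
    n_pairs: int
    n_discordant: int
    mean: float
    median: float
    sd: float
    rank_test_p: float | None = None
    insert_mean: float | None = None


def paired_intervals(
    results: Sequence[MappingResult],
    insert_sample: np.ndarray | None = None,
) -> PairedIntervalReport:
    """Outer distances of concordantly mapped clone ends on the reference.

    Pairs must land on the same reference sequence, on opposite strands and
    pointing toward each other; others are counted as discordant.  When an
    insert-length sample is supplied, the interval sizes are compared with a
    two-sided Wilcoxon rank-sum test.
    """
    by_id = {r.query_id: r for r in results if r.classification == "mapped"}
    clones: dict[str, dict[str, MappingResult]] = {}
    for qid, r in by_id.items():
        if "/" not in qid:
            continue
        cid, end = qid.rsplit("/", 1)
        clones.setdefault(cid, {})[end] = r
    sizes = []
    discordant = 0
    for cid, ends in clones.items():
        if "f" not in ends or "r" not in ends:
            continue
        hf, hr = ends["f"].best_hit, ends["r"].best_hit
        ok = (
            hf.reference_id == hr.reference_id
            and hf.strand != hr.strand
            and seqs.overlap_len((hf.ref_start, hf.ref_end), (hr.ref_start, hr.ref_end)) == 0
        )
        if ok:
            left, right = (hf, hr) if hf.ref_start <= hr.ref_start else (hr, hf)
            ok = left.strand == "+"  # ends must face each other
        if not ok:
            discordant += 1
            continue
        sizes.append(max(hf.ref_end, hr.ref_end) - min(hf.ref_start, hr.ref_start))
    arr = np.asarray(sizes, dtype=float)
    p = None
    imean = None
    if insert_sample is not None and arr.size:
        from scipy.stats import ranksums

        p = float(ranksums(arr, np.asarray(insert_sample, dtype=float)).pvalue)
        imean = float(np.mean(insert_sample))
    return PairedIntervalReport(
        sizes=arr,
        n_pairs=int(arr.size),
        n_discordant=discordant,
        mean=float(arr.mean()) if arr.size else float("nan"),
        median=float(np.median(arr)) if arr.size else float("nan"),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        rank_test_p=p,
        insert_mean=imean,
    )


def self_mapping_rate(
    genome: AnnotatedGenome,
    n: int,
    length_dist,
    mutation_rate: float,
    seed: int,
    params: AlignParams = AlignParams(),
) -> float:
    """Fraction of simulated fragments that classify as mapped when aligned
    back to their source genome (aligner sensitivity check)."""
    frags = simulate_bes_from_genome(genome, n, length_dist, mutation_rate, seed)
    index = ReferenceIndex.build(genome, k=params.k)
    n_mapped = 0
    for f in frags:
        hits = align_local(f, index, params, use_query_mask=False)
        if classify_bes(hits, query_id=f.record_id).classification == "mapped":
            n_mapped += 1
    return n_mapped / n


def write_blast_tabular(path: str | Path, hits: Iterable[AlignmentHit]) -> None:
    """12-column BLAST tabular dialect; coordinates 1-based closed, e-value
    is a placeholder."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_start + 1, h.query_end
            if h.strand == "+":
                ss, se = h.ref_start + 1, h.ref_end
            else:
                ss, se = h.ref_end, h.ref_start + 1
            gaps = 0  # gap opens not tracked separately in the summary
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.reference_id,
                        f"{100 * h.identity:.2f}",
                        h.aligned_columns,
                        h.mismatches,
                        gaps,
                        qs,
                        qe,
                        ss,
                        se,
                        ".",
                        h.score,
                    )
                )
                + "\n"
            )


def write_classification_tsv(path: str | Path, results: Sequence[MappingResult]) -> None:
    with open(path, "w") as fh:
        fh.write("query\tclass\tn_equal_best\treference\tstrand\tref_start\tref_end\tidentity\tcoverage\n")
        for r in results:
            if r.best_hit is None:
                fh.write(f"{r.query_id}\t{r.classification}\t0\t.\t.\t.\t.\t.\t.\n")
            else:
                h = r.best_hit
                fh.write(
                    f"{r.query_id}\t{r.classification}\t{r.n_equal_best}\t{h.reference_id}\t{h.strand}\t"
                    f"{h.ref_start + 1}\t{h.ref_end}\t{h.identity:.4f}\t{h.coverage:.4f}\n"
                )
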