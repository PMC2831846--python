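"""Synthetic genomes, diverged lineages, BAC clones and simulated end reads.

The generator emulates the composition of an AA-genome rice chromosome at
desk scale: a gene-bearing backbone with interspersed repeat families
(~39% repetitive by default, matching the repeat content of the japonica
reference), a diverged lineage produced by point substitutions plus large
segmental deletions that remove whole genes, BAC clones with a truncated-
normal insert-length distribution, and single-end "simulated BES" fragments
drawn with a Mersenne-Twister generator.

Every operation is deterministic given its seed, and deletions are recorded
in an :class:`EventLog` so downstream estimates can be checked against the
true number of lost genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import seqs

# Distribution specs are ("constant", v) | ("uniform", lo, hi) |
# ("normal", mu, sd) | ("empirical", values). Sampled lengths are >= 1.
DistSpec = tuple

_SENSE_CODONS = None  # lazily built list of 61 sense codons as code triples


def sample_dist(dist: DistSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "constant":
        out = np.full(n, dist[1], dtype=float)
    elif kind == "uniform":
        out = rng.uniform(dist[1], dist[2] + 1, size=n)
    elif kind == "normal":
        out = rng.normal(dist[1], dist[2], size=n)
    elif kind == "empirical":
        out = rng.choice(np.asarray(dist[1], dtype=float), size=n)
    else:
        raise ValueError(f"unknown distribution spec {dist!r}")
    return np.maximum(1, np.rint(out)).astype(np.int64)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int
    end: int
    family: str = "single"


@dataclass
class AnnotatedGenome:
    """Sequence plus gene and repeat interval tracks."""

    name: str
    codes: np.ndarray
    genes: list[Gene] = field(default_factory=list)
    repeats: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return int(self.codes.size)

    @property
    def repeat_fraction(self) -> float:
        if self.length == 0:
            return 0.0
        covered = seqs.merge_intervals([(s, e) for s, e, _ in self.repeats])
        return sum(e - s for s, e in covered) / self.length

    def sequence(self) -> str:
        return seqs.decode(self.codes)

    def gene_intervals(self) -> list[tuple[int, int]]:
        return [(g.start, g.end) for g in self.genes]


@dataclass(frozen=True)
class GenomeSpec:
    """Composition of the ancestral genome.

    ``repeat_families`` entries are (unit length bp, copy number); copy
    numbers act as relative weights and are rescaled so the realized repeat
    fraction hits ``target_repeat_fraction``.  ``gene_families`` entries are
    (family name, n members, tandem) and carve members out of ``n_genes``;
    remaining genes are singletons.
    """

    length: int = 2_000_000
    n_genes: int = 170
    gene_length_dist: DistSpec = ("uniform", 900, 2400)
    repeat_families: Sequence[tuple[int, int]] = ((500, 60), (1200, 25), (200, 120), (3000, 8))
    target_repeat_fraction: float = 0.39
    gc: float = 0.44
    gene_families: Sequence[tuple[str, int, bool]] = (("NBS-LRR-like", 12, True),)
    repeat_divergence: float = 0.05

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not (0 <= self.target_repeat_fraction < 1):
            raise ValueError("target_repeat_fraction must be in [0, 1)")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")


@dataclass(frozen=True)
class EvolutionSpec:
    """Divergence model: uniform substitutions, large segmental deletions,
    optional small indels (placed outside gene bodies)."""

    sub_rate: float = 0.0
    large_deletion_count: int = 0
    large_deletion_size_dist: DistSpec = ("uniform", 50_000, 150_000)
    small_indel_rate: float = 0.0
    small_indel_size_dist: DistSpec = ("uniform", 1, 30)
    seed: int = 0
    target_family: str | None = None  # bias deletions onto members of this gene family

    def validate(self) -> None:
        if self.sub_rate < 0 or self.small_indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.large_deletion_count < 0:
            raise ValueError("deletion count must be non-negative")


@dataclass(frozen=True)
class CloneSpec:
    n_clones: int = 5000
    insert_mean: int = 140_000
    insert_sd: int = 20_000
    end_length_dist: DistSpec = ("uniform", 300, 800)
    seed: int = 0

    def max_end_length(self) -> int:
        d = self.end_length_dist
        if d[0] == "constant":
            return int(d[1])
        if d[0] == "uniform":
            return int(d[2])
        if d[0] == "normal":
            return int(d[1] + 6 * d[2])
        return int(max(d[1]))

    def validate(self) -> None:
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        if self.insert_mean <= 2 * self.max_end_length():
            raise ValueError("insert_mean must exceed twice the maximum end length")


@dataclass
class EventLog:
    """Ground truth of an evolve_lineage call, in ancestral coordinates.

    Each event is (kind, start, end, size, gene_ids) with gene_ids a
    comma-joined list of the genes the event removed ('' otherwise).
    """

    events: list[tuple[str, int, int, int, str]] = field(default_factory=list)
    deleted_gene_ids: set[str] = field(default_factory=set)
    n_substitutions: int = 0

    def to_rows(self, chrom: str) -> list[tuple]:
        rows = [(k, chrom, s, e, sz, g) for k, s, e, sz, g in self.events]
        rows.append(("substitutions", chrom, 0, 0, self.n_substitutions, ""))
        return rows


@dataclass(frozen=True)
class BESRecord:
    """One end-sequence with clone identity and ground-truth provenance."""

    clone_id: str
    end: str  # 'f' | 'r' | 's' (single, simulated)
    codes: np.ndarray
    source_start: int
    source_end: int
    strand: str
    genome: str

    @property
    def record_id(self) -> str:
        return f"{self.clone_id}/{self.end}"

    @property
    def length(self) -> int:
        return int(self.codes.size)

    def sequence(self) -> str:
        return seqs.decode(self.codes)


class InfeasibleSpecError(ValueError):
    pass


def _random_background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _sense_codons() -> np.ndarray:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .molevol import STOP_CODONS

        cods = [
            (a, b, c)
            for a in range(4)
            for b in range(4)
            for c in range(4)
            if (a, b, c) not in STOP_CODONS
        ]
        _SENSE_CODONS = np.array(cods, dtype=np.uint8)
    return _SENSE_CODONS


def _random_gene(length: int, rng: np.random.Generator) -> np.ndarray:
    """In-frame coding sequence: ATG then random sense codons, no stops."""
    n_codons = max(2, length // 3)
    cods = _sense_codons()
    body = cods[rng.integers(0, len(cods), size=n_codons - 1)].reshape(-1)
    return np.concatenate((seqs.encode("ATG"), body)).astype(np.uint8)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Substitute each site with probability ``rate`` to a random *different* base."""
    out = codes.copy()
    hit = (rng.random(codes.size) < rate) & (codes < 4)
    idx = np.flatnonzero(hit)
    if idx.size:
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return out, int(idx.size)


def build_ancestral_genome(spec: GenomeSpec, seed: int) -> AnnotatedGenome:
    """Assemble genes, repeat-family copies and background into one sequence.

    Items (genes and tandem repeat arrays) are placed in random order with
    random background spacers, so annotation tracks never overlap and the
    realized repeat fraction equals the target up to rounding.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    gene_lengths = sample_dist(spec.gene_length_dist, spec.n_genes, rng) if spec.n_genes else np.empty(0, np.int64)
    # family labels for the first members, singletons for the rest
    labels: list[str] = []
    for fam, n_mem, _tandem in spec.gene_families:
        labels.extend([fam] * n_mem)
    if len(labels) > spec.n_genes:
        labels = labels[: spec.n_genes]
    labels.extend(["single"] * (spec.n_genes - len(labels)))

    gene_seqs = [_random_gene(int(l), rng) for l in gene_lengths]

    # Repeat copies: rescale the family copy numbers to the target fraction.
    base_total = sum(u * c for u, c in spec.repeat_families)
    items: list[tuple[str, object]] = []  # ("gene", (idx,)) or ("repeat", (fam, codes))
    if spec.target_repeat_fraction > 0 and base_total > 0:
        factor = spec.target_repeat_fraction * spec.length / base_total
        for fi, (unit_len, copies) in enumerate(spec.repeat_families):
            n_copies = max(1, int(round(copies * factor)))
            unit = _random_background(unit_len, spec.gc, rng)
            fam = f"rep{fi}"
            left = n_copies
            while left > 0:
                # tandem-and-dispersed: arrays of geometric size
                arr = min(left, int(rng.geometric(0.5)))
                copies_arr = [
                    _mutate(unit, spec.repeat_divergence, rng)[0] for _ in range(arr)
                ]
                items.append(("repeat_array", (fam, copies_arr)))
                left -= arr

    # tandem families become one contiguous block; everything else is placed alone
    gene_items: list[tuple[str, object]] = []
    used: set[int] = set()
    for fam, _n_mem, tandem in spec.gene_families:
        members = [j for j in range(spec.n_genes) if labels[j] == fam]
        if tandem and members:
            gene_items.append(("gene_block", members))
            used.update(members)
    for j in range(spec.n_genes):
        if j not in used:
            gene_items.append(("gene_block", [j]))
    items.extend(gene_items)

    def item_len(it):
        kind, payload = it
        if kind == "repeat_array":
            return sum(c.size for c in payload[1])
        return sum(gene_seqs[j].size for j in payload)

    total_items = sum(item_len(it) for it in items)
    if total_items > 0.98 * spec.length:
        raise InfeasibleSpecError(
            f"genes + repeats ({total_items} bp) exceed genome length {spec.length} bp"
        )

    perm = rng.permutation(len(items))
    items = [items[i] for i in perm]
    bg_total = spec.length - total_items
    spacers = rng.multinomial(bg_total, np.full(len(items) + 1, 1 / (len(items) + 1)))

    parts: list[np.ndarray] = []
    genes: list[Gene] = []
    repeats: list[tuple[int, int, str]] = []
    pos = 0

    def push(arr: np.ndarray):
        nonlocal pos
        parts.append(arr)
        pos += arr.size

    push(_random_background(int(spacers[0]), spec.gc, rng))
    for si, it in enumerate(items):
        kind, payload = it
        if kind == "repeat_array":
            fam, copies_arr = payload
            for c in copies_arr:
                repeats.append((pos, pos + c.size, fam))
                push(c)
        else:
            for j in payload:
                g = gene_seqs[j]
                genes.append(Gene(f"g{j:05d}", pos, pos + g.size, labels[j]))
                push(g)
        push(_random_background(int(spacers[si + 1]), spec.gc, rng))

    codes = np.concatenate(parts) if parts else np.empty(0, np.uint8)
    genes.sort(key=lambda g: g.start)
    repeats.sort()
    return AnnotatedGenome(name=f"anc_seed{seed}", codes=codes, genes=genes, repeats=repeats)


def evolve_lineage(genome: AnnotatedGenome, spec: EvolutionSpec) -> tuple[AnnotatedGenome, EventLog]:
    """Derive a lineage: large deletions, small indels, then substitutions.

    Genes overlapped by any deletion (even partially) are dropped from the
    derived annotation and recorded in the log; remaining annotation is
    lifted over.  Raises if the deletions would cover the whole genome.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = genome.length
    log = EventLog()

    # --- large deletions (ancestral coordinates) ---
    dels: list[tuple[int, int]] = []
    if spec.large_deletion_count > 0:
        sizes = sample_dist(spec.large_deletion_size_dist, spec.large_deletion_count, rng)
        targets: list[Gene] = []
        if spec.target_family is not None:
            targets = [g for g in genome.genes if g.family == spec.target_family]
        for i, size in enumerate(sizes):
            size = int(min(size, L))
            if targets and i < len(targets):
                g = targets[i]
                start = max(0, g.start - int(rng.integers(0, max(1, size - (g.end - g.start)) + 1)))
            else:
                start = int(rng.integers(0, max(1, L - size)))
            dels.append((start, min(L, start + size)))
        dels = seqs.merge_intervals(dels)
        if sum(e - s for s, e in dels) >= L:
            raise ValueError("deletions cover the entire genome")
    for s, e in dels:
        gids = sorted(
            g.gene_id for g in genome.genes if seqs.overlap_len((g.start, g.end), (s, e)) > 0
        )
        log.events.append(("large_deletion", s, e, e - s, ",".join(gids)))

    keep = ~seqs.intervals_to_mask(L, dels)
    # coordinate liftover: new position of ancestral p is cumsum(keep)[:p]
    shift = np.cumsum(keep) - keep  # new coord of each surviving ancestral base

    new_genes: list[Gene] = []
    for g in genome.genes:
        if any(seqs.overlap_len((g.start, g.end), d) > 0 for d in dels):
            log.deleted_gene_ids.add(g.gene_id)
        else:
            new_genes.append(replace(g, start=int(shift[g.start]), end=int(shift[g.end - 1]) + 1))
    new_repeats: list[tuple[int, int, str]] = []
    for s, e, fam in genome.repeats:
        surviving = np.flatnonzero(keep[s:e])
        if surviving.size:
            a, b = s + surviving[0], s + surviving[-1]
            new_repeats.append((int(shift[a]), int(shift[b]) + 1, fam))

    codes = genome.codes[keep]

    # --- small indels, outside gene bodies ---
    if spec.small_indel_rate > 0:
        n_ev = rng.poisson(spec.small_indel_rate * codes.size)
        if n_ev:
            gene_mask = seqs.intervals_to_mask(codes.size, [(g.start, g.end) for g in new_genes])
            sizes = sample_dist(spec.small_indel_size_dist, n_ev, rng)
            kinds = rng.random(n_ev) < 0.5  # True = deletion
            positions = rng.integers(0, codes.size, size=n_ev)
            # apply from right to left so earlier coordinates stay valid
            order = np.argsort(positions)[::-1]
            pieces = codes
            for j in order:
                p, sz = int(positions[j]), int(sizes[j])
                if gene_mask[p : p + sz + 1].any():
                    continue  # purifying selection keeps coding regions in frame
                if kinds[j]:
                    pieces = np.concatenate((pieces[:p], pieces[p + sz :]))
                    log.events.append(("small_deletion", p, p + sz, sz, ""))
                    delta = -min(sz, codes.size - p)
                else:
                    ins = _random_background(sz, 0.44, rng)
                    pieces = np.concatenate((pieces[:p], ins, pieces[p:]))
                    log.events.append(("small_insertion", p, p, sz, ""))
                    delta = sz
                new_genes = [
                    g if g.end <= p else replace(g, start=g.start + delta, end=g.end + delta)
                    for g in new_genes
                ]
                new_repeats = [
                    (s if e <= p else s + delta, e if e <= p else e + delta, fam)
                    for s, e, fam in new_repeats
                ]
            codes = pieces

    # --- substitutions ---
    if spec.sub_rate > 0:
        codes, nsub = _mutate(codes, spec.sub_rate, rng)
        log.n_substitutions = nsub

    derived = AnnotatedGenome(
        name=f"{genome.name}_evolved", codes=codes, genes=new_genes, repeats=new_repeats
    )
    return derived, log


def sample_bes(genome: AnnotatedGenome, spec: CloneSpec) -> list[BESRecord]:
    """Paired end reads of random BAC clones.

    Inserts are truncated-normal; the forward end is the genome subsequence
    at the proximal clone boundary, the reverse end the reverse complement
    of the distal boundary.
    """
    spec.validate()
    if genome.length <= spec.insert_mean:
        raise ValueError("genome shorter than mean insert")
    rng = np.random.default_rng(spec.seed)
    lo = 2 * spec.max_end_length()
    inserts = rng.normal(spec.insert_mean, spec.insert_sd, size=spec.n_clones)
    inserts = np.clip(np.rint(inserts), lo, genome.length - 1).astype(np.int64)
    starts = rng.integers(0, genome.length - inserts + 1)
    lf = sample_dist(spec.end_length_dist, spec.n_clones, rng)
    lr = sample_dist(spec.end_length_dist, spec.n_clones, rng)
    out: list[BESRecord] = []
    for i in range(spec.n_clones):
        s, e = int(starts[i]), int(starts[i] + inserts[i])
        cid = f"CL{i:06d}"
        out.append(
            BESRecord(cid, "f", genome.codes[s : s + int(lf[i])].copy(), s, s + int(lf[i]), "+", genome.name)
        )
        out.append(
            BESRecord(
                cid, "r", seqs.revcomp(genome.codes[e - int(lr[i]) : e]), e - int(lr[i]), e, "-", genome.name
            )
        )
    return out


def simulate_bes_from_genome(
    genome: AnnotatedGenome,
    n: int,
    length_dist: DistSpec,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> list[BESRecord]:
    """Single-end fragments sampled uniformly, Mersenne-Twister RNG.

    Fragments containing ambiguous bases are rejected and redrawn;
    substitutions are injected per site at ``mutation_rate`` to a random
    different base.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.Generator(np.random.MT19937(seed))
    lengths = sample_dist(length_dist, n, rng)
    if int(lengths.max()) > genome.length:
        raise ValueError("fragment length exceeds genome length")
    out: list[BESRecord] = []
    for i in range(n):
        ln = int(lengths[i])
        while True:
            s = int(rng.integers(0, genome.length - ln + 1))
            frag = genome.codes[s : s + ln]
            if not (frag >= 4).any():
                break
        frag = frag.copy()
        if mutation_rate > 0:
            frag, _ = _mutate(frag, mutation_rate, rng)
        out.append(BESRecord(f"sim{i:06d}", "s", frag, s, s + ln, "+", genome.name))
    return out


def write_bes_fasta(path, records: Sequence[BESRecord]) -> None:
    seqs.write_fasta(path, ((r.record_id, r.sequence()) for r in records))


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    h = np.uint64(master % (2**31))
    for ch in stage:
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**31 - 1))
    return int(h)
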