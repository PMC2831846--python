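"""Repeat masking and the minimum-unmasked / redundancy filters.

Two masking modes are supported.  *Library* mode masks every base covered
by a k-mer that occurs in a supplied repeat library (FASTA) or directly by
repeat intervals (BED).  *K-mer* mode needs no library: it counts canonical
k-mer multiplicities genome-wide and masks bases covered by any k-mer whose
multiplicity reaches a threshold.  Masking is soft (lower case on output):
downstream alignment seeds skip masked bases but extension may cross them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import seqs


@dataclass
class MaskedSequence:
    seq_id: str
    codes: np.ndarray
    mask: np.ndarray  # True = masked (repetitive)
    source: object = None  # optional provenance, e.g. a BESRecord

    @property
    def length(self) -> int:
        return int(self.codes.size)

    @property
    def unmasked_length(self) -> int:
        return int(self.length - np.count_nonzero(self.mask))

    @property
    def repeat_fraction(self) -> float:
        return float(np.count_nonzero(self.mask) / self.length) if self.length else 0.0

    def sequence(self) -> str:
        return seqs.decode(self.codes, self.mask)


class KmerMasker:
    """Masks bases covered by canonical k-mers from a frequent-k-mer set.

    Build the set either from a reference genome (multiplicity >= min_count)
    or from a repeat library (every k-mer).  The same masker can then be
    applied to the genome itself or to read sets sampled from related
    genomes, mirroring how one repeat library serves several species.
    """

    def __init__(self, kmer_set: np.ndarray, k: int):
        self.kmers = np.sort(np.asarray(kmer_set, dtype=np.int64))
        self.k = k

    @classmethod
    def from_counts(cls, sequences: Iterable[np.ndarray], k: int = 13, min_count: int = 3) -> "KmerMasker":
        vals = []
        for codes in sequences:
            v, ok = seqs.canonical_kmer_values(codes, k)
            vals.append(v[ok])
        allv = np.concatenate(vals) if vals else np.empty(0, np.int64)
        uniq, counts = np.unique(allv, return_counts=True)
        return cls(uniq[counts >= min_count], k)

    @classmethod
    def from_library(cls, library: Iterable[np.ndarray], k: int = 13) -> "KmerMasker":
        vals = []
        for codes in library:
            v, ok = seqs.canonical_kmer_values(codes, k)
            vals.append(v[ok])
        if not vals or all(v.size == 0 for v in vals):
            raise ValueError("empty repeat library")
        return cls(np.unique(np.concatenate(vals)), k)

    def mask(self, codes: np.ndarray) -> np.ndarray:
        m = np.zeros(codes.size, dtype=bool)
        if codes.size < self.k or self.kmers.size == 0:
            return m
        v, ok = seqs.canonical_kmer_values(codes, self.k)
        idx = np.searchsorted(self.kmers, v)
        idx[idx == self.kmers.size] = 0
        hit = ok & (self.kmers[idx] == v)
        starts = np.flatnonzero(hit)
        if starts.size:
            # cover [start, start+k) for every hit via difference array
            diff = np.zeros(codes.size + 1, dtype=np.int32)
            diff[starts] += 1
            diff[starts + self.k] -= 1
            m = np.cumsum(diff[:-1]) > 0
        return m


def mask_repeats(
    sequences: Sequence[tuple[str, np.ndarray]] | Sequence[MaskedSequence],
    mode: str = "kmer",
    k: int = 13,
    min_count: int = 3,
    library: Sequence[np.ndarray] | None = None,
    bed_intervals: dict[str, list[tuple[int, int]]] | None = None,
    masker: KmerMasker | None = None,
) -> list[MaskedSequence]:
    """Soft-mask a sequence set; idempotent (mask flags are unioned).

    mode="kmer": multiplicity counting over ``sequences`` themselves unless a
    prebuilt ``masker`` is given.  mode="library": requires ``library`` codes
    or explicit ``bed_intervals`` keyed by sequence id.
    """
    items: list[MaskedSequence] = []
    for s in sequences:
        if isinstance(s, MaskedSequence):
            items.append(s)
        else:
            name, codes = s
            items.append(MaskedSequence(name, np.asarray(codes, dtype=np.uint8), np.zeros(len(codes), bool)))

    if mode == "kmer":
        mk = masker or KmerMasker.from_counts((it.codes for it in items), k=k, min_count=min_count)
        for it in items:
            it.mask = it.mask | mk.mask(it.codes)
    elif mode == "library":
        if bed_intervals is not None:
            for it in items:
                ivs = bed_intervals.get(it.seq_id, [])
                it.mask = it.mask | seqs.intervals_to_mask(it.length, ivs)
        else:
            if not library:
                raise ValueError("empty repeat library in library mode")
            mk = KmerMasker.from_library(library, k=k)
            for it in items:
                it.mask = it.mask | mk.mask(it.codes)
    else:
        raise ValueError(f"unknown masking mode {mode!r}")
    return items


def aggregate_repeat_fraction(masked: Sequence[MaskedSequence]) -> float:
    total = sum(m.length for m in masked)
    return sum(np.count_nonzero(m.mask) for m in masked) / total if total else 0.0


def filter_short_unmasked(
    masked: Sequence[MaskedSequence], min_unmasked: int = 30
) -> tuple[list[MaskedSequence], list[MaskedSequence]]:
    """Partition by total unmasked length; < min_unmasked bp is excluded."""
    kept = [m for m in masked if m.unmasked_length >= min_unmasked]
    excluded = [m for m in masked if m.unmasked_length < min_unmasked]
    return kept, excluded


def flag_redundant(
    bes_set: Sequence[MaskedSequence],
    min_identity: float = 0.95,
    min_len: int = 100,
    min_hits: int = 3,
    seed_k: int = 13,
) -> set[str]:
    """Putative undetected repeats by the all-to-all redundancy rule.

    A BES is flagged when it aligns to ``min_hits`` or more *distinct other*
    BESs at >= min_identity over >= min_len aligned columns.
    """
    from . import mapping

    index = mapping.ReferenceIndex.build(
        [(m.seq_id, m.codes) for m in bes_set], k=seed_k, seed_unmasked_only=False
    )
    flagged: set[str] = set()
    for m in bes_set:
        hits = mapping.align_local(m, index, mapping.AlignParams(k=seed_k, max_candidates=32), use_query_mask=False)
        partners = {
            h.reference_id
            for h in hits
            if h.reference_id != m.seq_id
            and h.identity >= min_identity
            and h.aligned_columns >= min_len
        }
        if len(partners) >= min_hits:
            flagged.add(m.seq_id)
    return flagged


def summary_table(masked: Sequence[MaskedSequence]) -> list[tuple]:
    return [
        (m.seq_id, m.length, m.unmasked_length, round(m.repeat_fraction, 6)) for m in masked
    ]


def write_masked_fasta(path: str | Path, masked: Sequence[MaskedSequence]) -> None:
    seqs.write_fasta(path, ((m.seq_id, m.sequence()) for m in masked))


def read_masked_fasta(path: str | Path) -> list[MaskedSequence]:
    out = []
    for name, s in seqs.read_fasta(path):
        out.append(MaskedSequence(name, seqs.encode(s), seqs.mask_from_case(s)))
    return out
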