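"""Low-level sequence representation shared by every stage.

Nucleotides are held as ``numpy.uint8`` codes (A=0, C=1, G=2, T=3; anything
else, including N and the inter-sequence separator used by the aligner
index, is 4).  Case in FASTA carries the repeat mask: lower case = masked.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lower case

_CHAR = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CHAR_LOWER = np.frombuffer(b"acgtn", dtype=np.uint8)

COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (case-insensitive)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def mask_from_case(seq: str | bytes) -> np.ndarray:
    """Boolean mask array: True where the input letter is lower case."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    raw = np.frombuffer(seq, dtype=np.uint8)
    return (raw >= ord("a")) & (raw <= ord("z"))


def decode(codes: np.ndarray, mask: np.ndarray | None = None) -> str:
    """Codes back to a string; positions where ``mask`` is True are lower-cased."""
    out = _CHAR[codes]
    if mask is not None:
        out = np.where(mask, _CHAR_LOWER[codes], out)
    return out.tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes][::-1]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = (SeqRecord(Seq(s), id=name, description="") for name, s in records)
    SeqIO.write(recs, str(path), "fasta")


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every k-mer of ``codes``.

    Returns ``(values, valid)`` where ``values[i]`` encodes
    ``codes[i : i + k]`` and ``valid[i]`` is False when the window contains
    a non-ACGT code.  Empty arrays when the sequence is shorter than k.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    for i in range(k):
        vals = (vals << 2) | (codes[i : i + n] & 3)
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return vals, valid


def canonical_kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-canonical k-mer values (elementwise min of forward/revcomp)."""
    fwd, valid = kmer_values(codes, k)
    rc, _ = kmer_values(revcomp(codes), k)
    return np.minimum(fwd, rc[::-1]), valid


def intervals_to_mask(length: int, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s) : min(length, e)] = True
    return mask


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based half-open intervals."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader: (chrom, start, end, name); name '' when absent."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return rows


def write_bed(path: str | Path, rows: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def merge_intervals(intervals: Iterator[tuple[int, int]] | Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
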