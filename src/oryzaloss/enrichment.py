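"""Domain and functional-category enrichment among unmapped end sequences.

Consumes tabular protein-homology hits (BLAST-style 12-column rows or
already-parsed records), applies the homology filters (E-value threshold,
exclusion of possibly-mapped high-identity hits), builds per-domain 2x2
contingency tables over the distinct best-hit proteins of the mapped and
unmapped sets, and tests overrepresentation with Fisher's exact test.
Category profiles (GO-slim style) are compared per category with a
Bonferroni correction.  No search tools are invoked; the module is pure
bookkeeping plus exact tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import fisher_exact as _scipy_fisher

TRANSPOSON_CATEGORIES = frozenset({"GO:0003964", "GO:0004803"})


@dataclass(frozen=True)
class HomologyRecord:
    bes_id: str
    protein_id: str
    e_value: float
    identity_pct: float  # amino-acid identity, 0-100
    aligned_length: int

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        if not (0 <= self.identity_pct <= 100):
            raise ValueError("identity must be in [0, 100]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a: mapped with domain, b: mapped without, c: unmapped with,
    d: unmapped without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative contingency entry")


def read_homology_tsv(path: str | Path) -> list[HomologyRecord]:
    """Parse 'bes_id protein_id e_value identity_pct aligned_length' rows."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        try:
            out.append(HomologyRecord(f[0], f[1], float(f[2]), float(f[3]), int(f[4])))
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed homology row at line {ln}: {line!r}") from exc
    return out


def assign_homologs(
    hits: Iterable[HomologyRecord], e_max: float = 1e-10
) -> dict[str, HomologyRecord]:
    """Single best hit per BES: lowest E-value, ties by higher identity,
    then protein id; hits at or above e_max are not homologies at all."""
    best: dict[str, HomologyRecord] = {}
    for h in hits:
        if not h.e_value < e_max:
            continue
        cur = best.get(h.bes_id)
        if cur is None or (h.e_value, -h.identity_pct, h.protein_id) < (
            cur.e_value,
            -cur.identity_pct,
            cur.protein_id,
        ):
            best[h.bes_id] = h
    return best


def exclude_possibly_mapped(
    best_hits: Mapping[str, HomologyRecord], drop_fraction: float = 0.05
) -> tuple[dict[str, HomologyRecord], float]:
    """Drop the top ``drop_fraction`` of BESs by amino-acid identity.

    Guards against end sequences that fail to map only because the
    reference assembly is incomplete: a near-perfect protein match suggests
    the locus exists but was not sequenced.  Returns the retained hits and
    the realized identity cutoff (100 when nothing is dropped).  Exactly
    floor(drop_fraction * n) records go, ties broken by BES id.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    items = sorted(best_hits.items(), key=lambda kv: (-kv[1].identity_pct, kv[0]))
    n_drop = math.floor(drop_fraction * len(items))
    if n_drop == 0:
        return dict(best_hits), 100.0
    cutoff = items[n_drop - 1][1].identity_pct
    return dict(items[n_drop:]), float(cutoff)


def _filter_transposons(
    proteins: set[str], categories: Mapping[str, set[str]] | None
) -> set[str]:
    if categories is None:
        return proteins
    return {
        p for p in proteins if not (categories.get(p, set()) & TRANSPOSON_CATEGORIES)
    }


def domain_contingency(
    mapped_best: Mapping[str, HomologyRecord],
    unmapped_best: Mapping[str, HomologyRecord],
    domains: Mapping[str, set[str]],
    categories: Mapping[str, set[str]] | None = None,
) -> dict[str, ContingencyTable2x2]:
    """One 2x2 table per domain appearing in either protein set.

    Counts are over distinct best-hit proteins; proteins in transposon
    categories are removed before tabulation.
    """
    mapped_prot = _filter_transposons({h.protein_id for h in mapped_best.values()}, categories)
    unmapped_prot = _filter_transposons({h.protein_id for h in unmapped_best.values()}, categories)
    all_domains = set()
    for p in mapped_prot | unmapped_prot:
        all_domains |= domains.get(p, set())
    out = {}
    for dom in sorted(all_domains):
        a = sum(1 for p in mapped_prot if dom in domains.get(p, set()))
        c = sum(1 for p in unmapped_prot if dom in domains.get(p, set()))
        out[dom] = ContingencyTable2x2(a, len(mapped_prot) - a, c, len(unmapped_prot) - c)
    return out


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """(one-sided enrichment p, two-sided p) for a 2x2 table.

    The one-sided value tests overrepresentation of the domain in the
    *unmapped* set (the direction of interest for lost-gene candidates).
    """
    t = [[table.a, table.b], [table.c, table.d]]
    p_one = float(_scipy_fisher(t, alternative="less").pvalue)
    p_two = float(_scipy_fisher(t, alternative="two-sided").pvalue)
    return p_one, p_two


@dataclass
class CategoryComparison:
    category: str
    count_a: int
    count_b: int
    p: float
    p_bonferroni: float
    flagged: bool


def category_profile_compare(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    alpha: float = 0.05,
) -> list[CategoryComparison]:
    """Per-category Fisher tests between two category-count profiles.

    Each category is tested in-category vs not (two-sided), Bonferroni
    corrected over the number of categories tested.
    """
    cats = sorted(set(counts_a) | set(counts_b))
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    if tot_a == 0 or tot_b == 0:
        raise ValueError("empty category profile")
    out = []
    k = len(cats)
    for cat in cats:
        ca = counts_a.get(cat, 0)
        cb = counts_b.get(cat, 0)
        p = float(
            _scipy_fisher([[ca, tot_a - ca], [cb, tot_b - cb]], alternative="two-sided").pvalue
        )
        p_adj = min(1.0, p * k)
        out.append(CategoryComparison(cat, ca, cb, p, p_adj, p_adj < alpha))
    return out


def enrichment_table(
    tables: Mapping[str, ContingencyTable2x2],
    descriptions: Mapping[str, str] | None = None,
) -> "object":
    """Tidy per-domain report with both p-value conventions."""
    import pandas as pd

    rows = []
    for dom, t in tables.items():
        p_one, p_two = fisher_exact(t)
        rows.append(
            {
                "domain": dom,
                "description": (descriptions or {}).get(dom, ""),
                "mapped_with": t.a,
                "mapped_without": t.b,
                "unmapped_with": t.c,
                "unmapped_without": t.d,
                "p_one_sided": p_one,
                "p_two_sided": p_two,
            }
        )
    return pd.DataFrame(rows).sort_values("p_one_sided").reset_index(drop=True)
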