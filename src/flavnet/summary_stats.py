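"""Assembly-style length statistics and multi-database annotation merging.

These are the reporting computations behind the standard transcriptome
summary tables: total/average/N50 lengths of an assembly tier, and
per-database annotation counts with a redundancy-eliminated union, using an
E-value cutoff and a fixed database priority order to resolve conflicting
hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd

DEFAULT_PRIORITY: tuple[str, ...] = ("nr", "Swiss-Prot", "KEGG", "COG", "GO")
DEFAULT_EVALUE_CUTOFF = 1e-5


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (report convention, 2 decimals)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssemblyStats:
    total_number: int
    total_length: int
    n50: int
    average_length: float


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """Total, N50 and average length of a set of sequence lengths.

    N50 is the smallest length L such that sequences of length >= L hold at
    least half the total assembled bases (descending sort, cumulative sum).
    """
    lengths = list(lengths)
    if not lengths:
        raise ValueError("cannot summarize an empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    total = int(sum(lengths))
    half = total / 2
    running = 0
    n50 = lengths[0]
    for l in sorted(lengths, reverse=True):
        running += l
        if running >= half:
            n50 = l
            break
    return AssemblyStats(
        total_number=len(lengths),
        total_length=total,
        n50=int(n50),
        average_length=round_half_up(total / len(lengths)),
    )


@dataclass
class AnnotationRecord:
    """Per-gene best hits by database and the priority-resolved source."""

    gene_id: str
    hits: dict[str, tuple[str, float]]  # database -> (subject, evalue)
    primary_source: str | None


def merge_annotations(
    hit_tables: Mapping[str, pd.DataFrame],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> list[AnnotationRecord]:
    """Merge per-database hit tables into per-gene annotation records.

    Hits with e-value above the cutoff are discarded (kept iff
    evalue <= cutoff).  Within one database the lowest e-value wins, ties
    broken by higher bitscore then lexicographic subject id.  The primary
    source is the first database in ``priority`` with a retained hit.
    """
    unknown = set(hit_tables) - set(priority)
    if unknown:
        raise ValueError(
            f"databases {sorted(unknown)} missing from priority order {list(priority)}"
        )
    best: dict[str, dict[str, tuple[str, float]]] = {}
    for db, table in hit_tables.items():
        kept = table[table["evalue"] <= evalue_cutoff]
        if kept.empty:
            continue
        kept = kept.copy()
        if "bitscore" not in kept.columns:
            kept["bitscore"] = 0.0
        kept = kept.sort_values(
            ["query", "evalue", "bitscore", "subject"],
            ascending=[True, True, False, True],
            kind="stable",
        ).drop_duplicates("query", keep="first")
        for row in kept.itertuples(index=False):
            best.setdefault(row.query, {})[db] = (row.subject, float(row.evalue))
    records = []
    for gene in sorted(best):
        hits = best[gene]
        primary = next((db for db in priority if db in hits), None)
        records.append(AnnotationRecord(gene_id=gene, hits=hits, primary_source=primary))
    return records


def coverage_table(
    counts: Mapping[str, int], union_count: int, total_genes: int
) -> pd.DataFrame:
    """Per-database count/percent rows plus a redundancy-eliminated Total row.

    Percent = 100 · count / total_genes, half-up rounded to 2 decimals.
    """
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    if union_count > total_genes:
        raise ValueError("union count exceeds total genes")
    rows = [
        {"database": db, "count": int(c),
         "percent": round_half_up(100.0 * c / total_genes)}
        for db, c in counts.items()
    ]
    rows.append(
        {"database": "Total", "count": int(union_count),
         "percent": round_half_up(100.0 * union_count / total_genes)}
    )
    return pd.DataFrame(rows, columns=["database", "count", "percent"])


def annotation_coverage(
    records: Sequence[AnnotationRecord], total_genes: int
) -> pd.DataFrame:
    """Annotation coverage by database from merged records (each gene counted
    once in the union Total row)."""
    if total_genes < len(records):
        raise ValueError("total_genes smaller than the number of annotated genes")
    counts: dict[str, int] = {}
    for rec in records:
        for db in rec.hits:
            counts[db] = counts.get(db, 0) + 1
    union = sum(1 for rec in records if rec.hits)
    ordered = {db: counts[db] for db in DEFAULT_PRIORITY if db in counts}
    for db in counts:
        ordered.setdefault(db, counts[db])
    return coverage_table(ordered, union, total_genes)
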