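"""Curation harmonization: deduplication and contradiction removal.

Curated association tables merge several upstream sources, so the same link
often appears multiple times, and a disease–microbe pair can be reported
with both directions.  Harmonization collapses exact duplicates on the
association key and removes every pair reported in both directions — both
records are dropped, not arbitrated, since no vote rule is defensible for
literature curation counts of this kind.  Contradictions cannot arise in
production links (presence-only), so conflict scanning applies only to
disease–microbe records.

Output order is deterministic (sorted by key) so downstream score ranking
is reproducible.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple, Union

from .model import (
    Direction,
    DiseaseMicrobeAssociation,
    HarmonizationReport,
    ProductionLink,
)

Record = Union[DiseaseMicrobeAssociation, ProductionLink]


def deduplicate(records: Sequence[Record]) -> Tuple[List[Record], HarmonizationReport]:
    """Collapse exact duplicates on the association key.

    The key is (disease_id, microbe_taxid, direction) for disease–microbe
    records and (microbe_taxid, metabolite_id) for production links;
    evidence fields (PMID, method, names) are excluded, and the first
    occurrence's evidence is kept.
    """
    seen = {}
    for rec in records:
        seen.setdefault(rec.key, rec)
    out = [seen[k] for k in sorted(seen)]
    report = HarmonizationReport(
        records_in=len(records),
        records_out=len(out),
        duplicates_removed=len(records) - len(out),
    )
    return out, report


def remove_contradictions(
    records: Sequence[DiseaseMicrobeAssociation],
) -> Tuple[List[DiseaseMicrobeAssociation], HarmonizationReport]:
    """Drop every (disease, microbe) pair reported with both directions.

    Both directions are removed entirely; the dropped pairs are listed in
    the report so the rule can be audited.  Input should already be
    deduplicated.
    """
    directions = {}
    for rec in records:
        directions.setdefault((rec.disease_id, rec.microbe_taxid), set()).add(
            rec.direction
        )
    conflicted = sorted(
        pair for pair, dirs in directions.items() if len(dirs) == 2
    )
    conflicted_set = set(conflicted)
    out = [
        rec
        for rec in records
        if (rec.disease_id, rec.microbe_taxid) not in conflicted_set
    ]
    out.sort(key=lambda r: r.key)
    report = HarmonizationReport(
        records_in=len(records),
        records_out=len(out),
        duplicates_removed=0,
        contradictory_pairs_removed=conflicted,
    )
    return out, report


def harmonize_disease_microbe(
    records: Sequence[DiseaseMicrobeAssociation],
) -> Tuple[List[DiseaseMicrobeAssociation], HarmonizationReport]:
    """Deduplicate then remove contradictions; one combined report."""
    deduped, dedup_report = deduplicate(records)
    clean, conflict_report = remove_contradictions(deduped)
    report = HarmonizationReport(
        records_in=len(records),
        records_out=len(clean),
        duplicates_removed=dedup_report.duplicates_removed,
        contradictory_pairs_removed=conflict_report.contradictory_pairs_removed,
    )
    return clean, report


def harmonize_production(
    records: Sequence[ProductionLink],
) -> Tuple[List[ProductionLink], HarmonizationReport]:
    """Deduplicate production links (no direction, so no contradictions)."""
    return deduplicate(records)
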