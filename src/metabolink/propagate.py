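"""Genus→strain propagation of disease–microbe directions.

Sequencing surveys report disease associations at genus level, while
metabolic production tables work at strain/species level.  The bridging
assumption: if a genus is increased (decreased) in a disease, every strain
of that genus is increased (decreased).  Propagation is restricted to the
*strain universe* — the taxids present in the harmonized production table —
because strains without metabolic annotation cannot contribute producer
counts, and counting them would make the panel sizes depend on taxonomy-dump
completeness rather than on the inputs.

A taxid whose own rank is species, subspecies or strain counts as a
strain-level member; only its genus-rank ancestor matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .model import Direction, DiseaseMicrobeAssociation, ProductionLink
from .taxonomy import TaxonomyIndex

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseasePanel:
    """Propagated strain sets for one disease.

    The two sets are disjoint by construction (contradictory genus records
    were removed upstream).  `provenance` maps each strain to the genus that
    contributed it (one arbitrary-but-deterministic genus if several
    same-direction genera share the strain, which only happens for
    non-genus-rank inputs).
    """

    disease_id: str
    increased_strains: FrozenSet[int]
    decreased_strains: FrozenSet[int]
    provenance: Dict[int, int] = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.increased_strains)

    @property
    def N(self) -> int:
        return len(self.decreased_strains)


@dataclass
class StrainPanel:
    """Per-disease propagated strain sets plus skip/warning reports."""

    panels: Dict[str, DiseasePanel]
    unresolved_taxids: List[Tuple[str, int]] = field(default_factory=list)
    non_genus_taxids: List[Tuple[str, int]] = field(default_factory=list)
    empty_diseases: List[str] = field(default_factory=list)

    def __getitem__(self, disease_id: str) -> DiseasePanel:
        return self.panels[disease_id]

    def __iter__(self):
        return iter(self.panels.values())

    def __len__(self) -> int:
        return len(self.panels)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for panel in self.panels.values():
            for direction, strains in (
                (Direction.INCREASE, panel.increased_strains),
                (Direction.DECREASE, panel.decreased_strains),
            ):
                for strain in sorted(strains):
                    rows.append(
                        {
                            "disease_id": panel.disease_id,
                            "strain_taxid": strain,
                            "direction": direction.value,
                            "source_genus_taxid": panel.provenance.get(strain, ""),
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["disease_id", "strain_taxid", "direction", "source_genus_taxid"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def strain_universe(links: Sequence[ProductionLink]) -> Set[int]:
    """Distinct microbe taxids of the (harmonized) production table."""
    return {link.microbe_taxid for link in links}


def strains_of_genus(
    taxonomy: TaxonomyIndex,
    genus_taxid: int,
    universe: Iterable[int],
) -> Set[int]:
    """Universe members whose genus-rank ancestor is `genus_taxid`.

    If `genus_taxid` is not itself genus-rank, its own genus-rank ancestor
    is used (with a warning); this tolerates curation tables that slip in
    species-level disease associations.
    """
    if genus_taxid not in taxonomy:
        from .model import ResolutionError

        raise ResolutionError(f"genus taxid {genus_taxid} not in taxonomy")
    target = genus_taxid
    if taxonomy.rank(genus_taxid) != "genus":
        anc = taxonomy.genus_of(genus_taxid)
        if anc is not None:
            logger.warning(
                "taxid %d has rank %r, using genus ancestor %d",
                genus_taxid,
                taxonomy.rank(genus_taxid),
                anc,
            )
            target = anc
        else:
            logger.warning(
                "taxid %d has rank %r and no genus ancestor; matching its own subtree",
                genus_taxid,
                taxonomy.rank(genus_taxid),
            )
            return {
                s for s in universe if s in taxonomy and genus_taxid in taxonomy.lineage(s)
            }
    return {
        s for s in universe if s in taxonomy and taxonomy.genus_of(s) == target
    }


def propagate_directions(
    assocs: Sequence[DiseaseMicrobeAssociation],
    taxonomy: TaxonomyIndex,
    universe: Iterable[int],
) -> StrainPanel:
    """Expand genus-level directions to strain panels per disease.

    Input must be contradiction-free.  Unresolvable genus taxids are
    collected into a skip report rather than being fatal (curation tables
    routinely contain retired taxids).  Diseases whose genera expand to
    empty strain sets are retained with empty panels and flagged.
    """
    universe = set(universe)
    by_disease: Dict[str, Dict[Direction, Set[int]]] = {}
    provenance: Dict[str, Dict[int, int]] = {}
    unresolved: List[Tuple[str, int]] = []
    non_genus: List[Tuple[str, int]] = []

    for rec in assocs:
        bucket = by_disease.setdefault(
            rec.disease_id, {Direction.INCREASE: set(), Direction.DECREASE: set()}
        )
        prov = provenance.setdefault(rec.disease_id, {})
        if rec.microbe_taxid not in taxonomy:
            unresolved.append((rec.disease_id, rec.microbe_taxid))
            continue
        if taxonomy.rank(rec.microbe_taxid) != "genus":
            non_genus.append((rec.disease_id, rec.microbe_taxid))
        members = strains_of_genus(taxonomy, rec.microbe_taxid, universe)
        bucket[rec.direction].update(members)
        for strain in sorted(members):
            prov.setdefault(strain, rec.microbe_taxid)

    panels: Dict[str, DiseasePanel] = {}
    empty: List[str] = []
    for disease_id in sorted(by_disease):
        inc = frozenset(by_disease[disease_id][Direction.INCREASE])
        dec = frozenset(by_disease[disease_id][Direction.DECREASE])
        if not inc and not dec:
            empty.append(disease_id)
        panels[disease_id] = DiseasePanel(
            disease_id=disease_id,
            increased_strains=inc,
            decreased_strains=dec,
            provenance=provenance[disease_id],
        )
    if empty:
        logger.warning("diseases with empty strain panels: %s", ", ".join(empty))
    return StrainPanel(
        panels=panels,
        unresolved_taxids=unresolved,
        non_genus_taxids=non_genus,
        empty_diseases=empty,
    )
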