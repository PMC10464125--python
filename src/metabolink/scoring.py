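"""Association strength and confidence scoring of disease–metabolite pairs.

For a disease with M increased and N decreased strains (after genus→strain
propagation), and a metabolite produced by m of the increased and n of the
decreased strains, the association strength score is

    S_as = m/M − n/N

and the confidence score is

    S_ac = (m + n) · |S_as|.

A positive S_as ties the metabolite to disease-enriched microbes (potential
disease marker); a negative S_as ties it to disease-depleted microbes
(candidate drug / diagnostic marker).  A pair is *meaningful* when
|S_as| > 0.05 and S_ac > 1, both strict.

A ratio with zero denominator contributes 0: diseases whose microbes are
all in one direction still score (their pairs come out exactly ±1), so the
formula must be total.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Optional, Sequence, Tuple

from .harmonize import harmonize_disease_microbe, harmonize_production
from .model import (
    AssociationLabel,
    CountQuad,
    DiseaseMicrobeAssociation,
    DiseaseSummary,
    ProductionLink,
    ScoredAssociation,
    Thresholds,
)
from .propagate import StrainPanel, propagate_directions, strain_universe
from .taxonomy import TaxonomyIndex


def association_strength(q: CountQuad) -> float:
    """S_as = m/M − n/N, with zero-denominator terms contributing 0."""
    pos = q.m / q.M if q.M > 0 else 0.0
    neg = q.n / q.N if q.N > 0 else 0.0
    return pos - neg


def confidence(q: CountQuad, s_as: Optional[float] = None) -> float:
    """S_ac = (m+n)·|S_as|."""
    if s_as is None:
        s_as = association_strength(q)
    return (q.m + q.n) * abs(s_as)


def label_for(s_as: float) -> AssociationLabel:
    if s_as > 0:
        return AssociationLabel.MARKER_LIKE
    if s_as < 0:
        return AssociationLabel.DRUG_LIKE
    return AssociationLabel.NEUTRAL


def classify(
    disease_id: str,
    metabolite_id: int,
    q: CountQuad,
    thresholds: Thresholds = Thresholds(),
    metabolite_name: Optional[str] = None,
) -> ScoredAssociation:
    """Score one pair and attach the meaningful flag and sign label."""
    s_as = association_strength(q)
    s_ac = confidence(q, s_as)
    meaningful = abs(s_as) > thresholds.s_as_abs_min and s_ac > thresholds.s_ac_min
    return ScoredAssociation(
        disease_id=disease_id,
        metabolite_id=metabolite_id,
        counts=q,
        s_as=s_as,
        s_ac=s_ac,
        meaningful=meaningful,
        label=label_for(s_as),
        metabolite_name=metabolite_name,
    )


def tally_counts(
    panel: StrainPanel, links: Sequence[ProductionLink]
) -> Dict[Tuple[str, int], CountQuad]:
    """Count producing strains per (disease, metabolite) pair.

    Only pairs with m + n ≥ 1 are emitted: a pair no panel strain produces
    has S_ac = 0, can never pass the strict threshold, and emitting all of
    them would bloat output quadratically.
    """
    producers: Dict[int, set] = defaultdict(set)
    for link in links:
        producers[link.metabolite_id].add(link.microbe_taxid)

    out: Dict[Tuple[str, int], CountQuad] = {}
    for disease_panel in panel:
        M, N = disease_panel.M, disease_panel.N
        for metabolite_id in sorted(producers):
            strains = producers[metabolite_id]
            m = len(strains & disease_panel.increased_strains)
            n = len(strains & disease_panel.decreased_strains)
            if m + n >= 1:
                out[(disease_panel.disease_id, metabolite_id)] = CountQuad(m, n, M, N)
    return out


def _rank_key(s: ScoredAssociation) -> tuple:
    # per disease: ascending s_as, ties by descending s_ac then metabolite_id,
    # so "k-th strongest negative association" is well defined
    return (s.disease_id, s.s_as, -s.s_ac, s.metabolite_id)


def score_pairs(
    counts: Dict[Tuple[str, int], CountQuad],
    thresholds: Thresholds = Thresholds(),
    metabolite_names: Optional[Dict[int, str]] = None,
) -> List[ScoredAssociation]:
    names = metabolite_names or {}
    scored = [
        classify(d, c, q, thresholds, metabolite_name=names.get(c))
        for (d, c), q in counts.items()
    ]
    scored.sort(key=_rank_key)
    return scored


def score_all(
    dm_records: Sequence[DiseaseMicrobeAssociation],
    mm_records: Sequence[ProductionLink],
    taxonomy: TaxonomyIndex,
    thresholds: Thresholds = Thresholds(),
    meaningful_only: bool = False,
) -> List[ScoredAssociation]:
    """End-to-end scoring: harmonize → propagate → tally → score → classify.

    Output is sorted per disease by ascending S_as (most drug-like first),
    ties broken by descending S_ac then ascending metabolite id.
    """
    dm_clean, _ = harmonize_disease_microbe(dm_records)
    mm_clean, _ = harmonize_production(mm_records)
    universe = strain_universe(mm_clean)
    panel = propagate_directions(dm_clean, taxonomy, universe)
    counts = tally_counts(panel, mm_clean)
    names = {
        link.metabolite_id: link.metabolite_name
        for link in mm_clean
        if link.metabolite_name
    }
    scored = score_pairs(counts, thresholds, metabolite_names=names)
    if meaningful_only:
        scored = [s for s in scored if s.meaningful]
    return scored


def summarize_by_disease(
    scored: Sequence[ScoredAssociation],
) -> List[DiseaseSummary]:
    """Mean S_as per disease over all emitted pairs, descending by mean."""
    by_disease: Dict[str, List[float]] = defaultdict(list)
    for s in scored:
        by_disease[s.disease_id].append(s.s_as)
    summaries = [
        DiseaseSummary(
            disease_id=d, mean_s_as=sum(v) / len(v), n_metabolites=len(v)
        )
        for d, v in by_disease.items()
    ]
    summaries.sort(key=lambda s: (-s.mean_s_as, s.disease_id))
    return summaries
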