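"""Seeded generator of complete synthetic input bundles.

Produces the four canonical tables (lineage, disease–microbe,
microbe–metabolite, validation labels) with known ground truth, so every
pipeline stage is testable without any external download.  The taxonomy is
a rooted three-level tree (root → genera → strains), which is all the
genus→strain propagation rule ever inspects.

Planted signal: a *drug-like* metabolite is produced exclusively by every
decreased strain of a designated disease (so it attains the minimum
possible S_as = −n/N for that disease); a *marker-like* metabolite is the
mirror image on increased strains.  Validation labels are derived from the
planted ground truth, optionally direction-flipped with probability
`label_noise`.

Randomness comes from a single seed; per-table sub-streams are derived
with ``numpy.random.SeedSequence.spawn`` so, for example, adding
metabolites never perturbs the taxonomy draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import io as mio
from .model import (
    AssociationLabel,
    Direction,
    DiseaseMicrobeAssociation,
    ExperimentalLabel,
    GenerationError,
    ObservedDirection,
    ProductionLink,
    ScoredAssociation,
    Thresholds,
)
from .scoring import score_all
from .taxonomy import TaxonNode, TaxonomyIndex

ROOT_TAXID = 1
_GENUS_BASE = 100
_STRAIN_BASE = 100_000
_STRAIN_STRIDE = 1_000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe a moderate desk-scale instance: five diseases over
    ten genera of three strains each, fifty metabolites with a 10%
    background production density, balanced direction frequencies, and two
    planted metabolites of each kind with noise-free labels.
    """

    n_diseases: int = 5
    n_genera: int = 10
    strains_per_genus: Union[int, Tuple[int, int]] = 3
    n_metabolites: int = 50
    p_increase: float = 0.5
    density_assoc: float = 0.4
    density_prod: float = 0.1
    n_planted_drug_like: int = 2
    n_planted_marker_like: int = 2
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in ("p_increase", "density_assoc", "density_prod", "label_noise"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be in [0, 1], got {v}")
        for c in (
            "n_diseases",
            "n_genera",
            "n_metabolites",
            "n_planted_drug_like",
            "n_planted_marker_like",
        ):
            if getattr(self, c) < 0:
                raise ValueError(f"{c} must be non-negative")
        if self.n_planted_drug_like + self.n_planted_marker_like > self.n_metabolites:
            raise ValueError("planted metabolite counts exceed n_metabolites")

    @property
    def strain_range(self) -> Tuple[int, int]:
        if isinstance(self.strains_per_genus, int):
            return (self.strains_per_genus, self.strains_per_genus)
        lo, hi = self.strains_per_genus
        return (int(lo), int(hi))


@dataclass(frozen=True)
class PlantedMetabolite:
    """Ground truth for one planted metabolite."""

    metabolite_id: int
    disease_id: str
    intended_sign: int  # +1 marker-like, -1 drug-like
    producer_taxids: frozenset

    @property
    def kind(self) -> str:
        return "marker_like" if self.intended_sign > 0 else "drug_like"


@dataclass
class SyntheticBundle:
    """A complete generated input set plus its ground truth."""

    config: SimConfig
    taxonomy: TaxonomyIndex
    lineage_nodes: List[TaxonNode]
    disease_microbe: List[DiseaseMicrobeAssociation]
    microbe_metabolite: List[ProductionLink]
    labels: List[ExperimentalLabel]
    ground_truth: List[PlantedMetabolite]

    def write(self, out_dir) -> Dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "lineage": out_dir / "lineage.tsv",
            "disease_microbe": out_dir / "disease_microbe.tsv",
            "microbe_metabolite": out_dir / "microbe_metabolite.tsv",
            "validation": out_dir / "validation.tsv",
            "ground_truth": out_dir / "ground_truth.tsv",
        }
        pd.DataFrame(
            [
                {
                    "taxid": n.taxid,
                    "parent_taxid": n.parent_taxid,
                    "rank": n.rank,
                    "name": n.name,
                }
                for n in self.lineage_nodes
            ],
            columns=["taxid", "parent_taxid", "rank", "name"],
        ).to_csv(paths["lineage"], sep="\t", index=False)
        mio.write_disease_microbe_table(self.disease_microbe, paths["disease_microbe"])
        mio.write_microbe_metabolite_table(
            self.microbe_metabolite, paths["microbe_metabolite"]
        )
        mio.write_validation_table(self.labels, paths["validation"])
        pd.DataFrame(
            [
                {
                    "metabolite_id": g.metabolite_id,
                    "disease_id": g.disease_id,
                    "intended_sign": g.intended_sign,
                    "producer_taxids": ",".join(map(str, sorted(g.producer_taxids))),
                }
                for g in self.ground_truth
            ],
            columns=["metabolite_id", "disease_id", "intended_sign", "producer_taxids"],
        ).to_csv(paths["ground_truth"], sep="\t", index=False)
        return paths


def _disease_id(i: int) -> str:
    return f"D{i + 1:06d}"


def generate_dataset(cfg: SimConfig) -> SyntheticBundle:
    """Generate one bundle; identical config (incl. seed) ⇒ identical bundle."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_tax, rng_assoc, rng_prod, rng_label = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # --- taxonomy: root → genera → strains ---------------------------------
    nodes = [TaxonNode(ROOT_TAXID, ROOT_TAXID, "no rank", "root")]
    genus_taxids: List[int] = []
    strains_of: Dict[int, List[int]] = {}
    lo, hi = cfg.strain_range
    for g in range(cfg.n_genera):
        genus = _GENUS_BASE + g
        genus_taxids.append(genus)
        nodes.append(TaxonNode(genus, ROOT_TAXID, "genus", f"Genus{g + 1}"))
        n_strains = int(rng_tax.integers(lo, hi + 1))
        members = []
        for s in range(n_strains):
            strain = _STRAIN_BASE + g * _STRAIN_STRIDE + s
            members.append(strain)
            nodes.append(
                TaxonNode(strain, genus, "strain", f"Genus{g + 1} strain {s + 1}")
            )
        strains_of[genus] = members
    taxonomy = TaxonomyIndex(nodes)

    # --- disease–genus associations ----------------------------------------
    diseases = [_disease_id(i) for i in range(cfg.n_diseases)]
    dm_records: List[DiseaseMicrobeAssociation] = []
    genus_direction: Dict[Tuple[str, int], Direction] = {}
    for d in diseases:
        for genus in genus_taxids:
            if rng_assoc.random() < cfg.density_assoc:
                direction = (
                    Direction.INCREASE
                    if rng_assoc.random() < cfg.p_increase
                    else Direction.DECREASE
                )
                genus_direction[(d, genus)] = direction
                dm_records.append(
                    DiseaseMicrobeAssociation(
                        disease_id=d,
                        microbe_taxid=genus,
                        direction=direction,
                        disease_name=f"Disease {d}",
                        microbe_name=taxonomy.name(genus),
                    )
                )

    # propagated panels, used to place planted producers
    panel_strains: Dict[str, Dict[Direction, List[int]]] = {
        d: {Direction.INCREASE: [], Direction.DECREASE: []} for d in diseases
    }
    for (d, genus), direction in genus_direction.items():
        panel_strains[d][direction].extend(strains_of[genus])

    # --- planted metabolites -----------------------------------------------
    n_planted = cfg.n_planted_drug_like + cfg.n_planted_marker_like
    planted_cids = list(range(cfg.n_metabolites - n_planted + 1, cfg.n_metabolites + 1))
    kinds = [-1] * cfg.n_planted_drug_like + [1] * cfg.n_planted_marker_like
    ground_truth: List[PlantedMetabolite] = []
    planted_links: List[ProductionLink] = []
    cursor = {-1: 0, 1: 0}
    for cid, sign in zip(planted_cids, kinds):
        need = Direction.DECREASE if sign < 0 else Direction.INCREASE
        feasible = [d for d in diseases if panel_strains[d][need]]
        if not feasible:
            raise GenerationError(
                f"no disease has {need.value}d strains to host planted "
                f"{'drug' if sign < 0 else 'marker'}-like metabolite CID {cid}"
            )
        disease = feasible[cursor[sign] % len(feasible)]
        cursor[sign] += 1
        producers = sorted(panel_strains[disease][need])
        for strain in producers:
            planted_links.append(
                ProductionLink(
                    microbe_taxid=strain,
                    metabolite_id=cid,
                    microbe_name=taxonomy.name(strain),
                    metabolite_name=f"planted_{'drug' if sign < 0 else 'marker'}_{cid}",
                )
            )
        ground_truth.append(
            PlantedMetabolite(
                metabolite_id=cid,
                disease_id=disease,
                intended_sign=sign,
                producer_taxids=frozenset(producers),
            )
        )

    # --- background production links (planted CIDs stay exclusive) --------
    all_strains = [s for genus in genus_taxids for s in strains_of[genus]]
    background_cids = list(range(1, cfg.n_metabolites - n_planted + 1))
    mm_records: List[ProductionLink] = []
    if all_strains and background_cids:
        draw = rng_prod.random((len(all_strains), len(background_cids)))
        for i, strain in enumerate(all_strains):
            for j, cid in enumerate(background_cids):
                if draw[i, j] < cfg.density_prod:
                    mm_records.append(
                        ProductionLink(
                            microbe_taxid=strain,
                            metabolite_id=cid,
                            microbe_name=taxonomy.name(strain),
                            metabolite_name=f"metabolite_{cid}",
                        )
                    )
    mm_records.extend(planted_links)
    mm_records.sort(key=lambda r: r.key)

    # --- validation labels from ground truth -------------------------------
    labels: List[ExperimentalLabel] = []
    for g in ground_truth:
        observed = ObservedDirection.UP if g.intended_sign > 0 else ObservedDirection.DOWN
        if rng_label.random() < cfg.label_noise:
            observed = observed.flipped()
        labels.append(
            ExperimentalLabel(
                disease_id=g.disease_id,
                metabolite_id=g.metabolite_id,
                observed_direction=observed,
            )
        )

    return SyntheticBundle(
        config=cfg,
        taxonomy=taxonomy,
        lineage_nodes=nodes,
        disease_microbe=dm_records,
        microbe_metabolite=mm_records,
        labels=labels,
        ground_truth=ground_truth,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    """Outcome of a planted-signal recovery experiment."""

    n_planted: int
    n_recovered: int
    false_top_k: float  # fraction of non-planted pairs among per-disease top-k

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 0.0


def recovery_experiment(
    cfg: SimConfig, thresholds: Thresholds = Thresholds()
) -> RecoveryMetrics:
    """Generate, score, and match scored output against the ground truth.

    A planted metabolite is *recovered* when its (disease, metabolite) pair
    is emitted, meaningful under `thresholds`, and carries the intended
    sign.  The false-top-k rate looks, for each disease hosting k planted
    metabolites of a kind, at the k most extreme meaningful scores of the
    matching sign and reports the fraction that are not planted.
    """
    bundle = generate_dataset(cfg)
    scored = score_all(
        bundle.disease_microbe, bundle.microbe_metabolite, bundle.taxonomy, thresholds
    )
    by_pair: Dict[Tuple[str, int], ScoredAssociation] = {
        (s.disease_id, s.metabolite_id): s for s in scored
    }

    n_recovered = 0
    for g in bundle.ground_truth:
        s = by_pair.get((g.disease_id, g.metabolite_id))
        if s is not None and s.meaningful and np.sign(s.s_as) == g.intended_sign:
            n_recovered += 1

    planted_by_group: Dict[Tuple[str, int], set] = {}
    for g in bundle.ground_truth:
        planted_by_group.setdefault((g.disease_id, g.intended_sign), set()).add(
            g.metabolite_id
        )
    selected = 0
    false_hits = 0
    for (disease, sign), cids in planted_by_group.items():
        k = len(cids)
        candidates = [
            s
            for s in scored
            if s.disease_id == disease and s.meaningful and np.sign(s.s_as) == sign
        ]
        candidates.sort(key=lambda s: (sign * -s.s_as, -s.s_ac, s.metabolite_id))
        for s in candidates[:k]:
            selected += 1
            if s.metabolite_id not in cids:
                false_hits += 1
    false_top_k = false_hits / selected if selected else 0.0

    return RecoveryMetrics(
        n_planted=len(bundle.ground_truth),
        n_recovered=n_recovered,
        false_top_k=false_top_k,
    )
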