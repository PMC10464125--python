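import pytest

from metabolink.model import Direction, DiseaseMicrobeAssociation, ProductionLink
from metabolink.taxonomy import TaxonNode, TaxonomyIndex


def make_taxonomy(genus_strains):
    """Build a root→genus→strain TaxonomyIndex.

    `genus_strains`: {genus_taxid: [strain_taxids]}.
    """
    nodes = [TaxonNode(1, 1, "no rank", "root")]
    for genus, strains in genus_strains.items():
        nodes.append(TaxonNode(genus, 1, "genus", f"Genus{genus}"))
        for s in strains:
            nodes.append(TaxonNode(s, genus, "strain", f"strain{s}"))
    return TaxonomyIndex(nodes)


def dm(disease, taxid, direction):
    return DiseaseMicrobeAssociation(
        disease_id=disease,
        microbe_taxid=taxid,
        direction=Direction.INCREASE if direction == "increase" else Direction.DECREASE,
    )


def pl(taxid, cid):
    return ProductionLink(microbe_taxid=taxid, metabolite_id=cid)


@pytest.fixture
def small_taxonomy():
    """Two genera: 853 with strains 8531/8532, 820 with strains 8201-8203."""
    return make_taxonomy({853: [8531, 8532], 820: [8201, 8202, 8203]})


@pytest.fixture
def records_to_tuples():
    def _convert(records):
        return [(r.disease_id, r.microbe_taxid, r.direction.value) for r in records]

    return _convert
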