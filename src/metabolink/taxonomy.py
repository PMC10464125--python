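"""Taxonomy lineage index with ancestor-at-rank queries.

Supports two on-disk dialects: a simplified four-column TSV
(taxid, parent_taxid, rank, name) and the NCBI taxdump pair
(nodes.dmp / names.dmp, pipe-with-tab delimited, scientific names only).
Both parse to the same in-memory index, so downstream code never sees the
dialect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Optional, Set, Tuple

from .model import ResolutionError, TaxonomyStructureError


class LineageDialect(enum.Enum):
    SIMPLE_TSV = "simple_tsv"
    NCBI_TAXDUMP = "ncbi_taxdump"


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str


class TaxonomyIndex:
    """taxid → (parent, rank, name) with genus-membership queries.

    Construction validates the structure: every parent must exist and the
    parent chain from any node must terminate at a root (a node that is its
    own parent, as in the NCBI dump) without cycles.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: Dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise TaxonomyStructureError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        self._check_structure()

    def _check_structure(self) -> None:
        orphans = sorted(
            (n.taxid, n.parent_taxid)
            for n in self._nodes.values()
            if n.parent_taxid not in self._nodes
        )
        if orphans:
            detail = ", ".join(f"{t}->missing {p}" for t, p in orphans)
            raise TaxonomyStructureError(f"orphan parent references: {detail}")
        roots = sorted(
            n.taxid for n in self._nodes.values() if n.parent_taxid == n.taxid
        )
        if len(roots) > 1:
            # a self-parent node other than the single root is a degenerate cycle
            raise TaxonomyStructureError(
                f"multiple self-parent nodes (cycle): taxids {roots}"
            )
        if self._nodes and not roots:
            raise TaxonomyStructureError("no root node (parent == self) found")
        ok: Set[int] = set()
        for taxid in self._nodes:
            seen = []
            cur = taxid
            while cur not in ok:
                node = self._nodes[cur]
                if node.parent_taxid == cur:  # root
                    break
                if cur in seen:
                    raise TaxonomyStructureError(
                        f"cycle detected in lineage involving taxid {cur}"
                    )
                seen.append(cur)
                cur = node.parent_taxid
            ok.update(seen)
            ok.add(cur)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TaxonomyIndex):
            return NotImplemented
        return self._nodes == other._nodes

    def _get(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise ResolutionError(f"taxid {taxid} not in taxonomy") from None

    def parent(self, taxid: int) -> int:
        return self._get(taxid).parent_taxid

    def rank(self, taxid: int) -> str:
        return self._get(taxid).rank

    def name(self, taxid: int) -> str:
        return self._get(taxid).name

    def lineage(self, taxid: int) -> Tuple[int, ...]:
        """Taxids from `taxid` up to and including the root."""
        out = [taxid]
        node = self._get(taxid)
        while node.parent_taxid != node.taxid:
            node = self._get(node.parent_taxid)
            out.append(node.taxid)
        return tuple(out)

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """The ancestor of `taxid` (inclusive) holding `rank`, or None."""
        for anc in self.lineage(taxid):
            if self._nodes[anc].rank == rank:
                return anc
        return None

    def genus_of(self, taxid: int) -> Optional[int]:
        return self.ancestor_at_rank(taxid, "genus")

    def taxids(self) -> Iterable[int]:
        return self._nodes.keys()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_simple_tsv(cls, path) -> "TaxonomyIndex":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"taxid", "parent_taxid", "rank", "name"}
        missing = required - set(df.columns)
        if missing:
            raise TaxonomyStructureError(
                f"{path}: missing lineage columns {sorted(missing)}"
            )
        nodes = [
            TaxonNode(int(r.taxid), int(r.parent_taxid), r.rank, r.name)
            for r in df.itertuples(index=False)
        ]
        return cls(nodes)

    @classmethod
    def from_taxdump(cls, directory) -> "TaxonomyIndex":
        """Parse nodes.dmp / names.dmp from a taxdump directory."""
        directory = Path(directory)
        nodes_path = directory / "nodes.dmp"
        names_path = directory / "names.dmp"
        for p in (nodes_path, names_path):
            if not p.exists():
                raise TaxonomyStructureError(f"taxdump file not found: {p}")

        names: Dict[int, str] = {}
        for fields in _iter_dmp(names_path):
            # fields: taxid | name_txt | unique name | name class
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[int(fields[0])] = fields[1]

        nodes = []
        for fields in _iter_dmp(nodes_path):
            taxid = int(fields[0])
            nodes.append(
                TaxonNode(taxid, int(fields[1]), fields[2], names.get(taxid, ""))
            )
        return cls(nodes)


def _iter_dmp(path: Path):
    """Yield field lists from an NCBI .dmp file (``\\t|\\t`` separators)."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            line = line.rstrip("|").rstrip("\t")
            yield [f.strip("\t") for f in line.split("\t|")]


def read_lineage(path, dialect: LineageDialect = LineageDialect.SIMPLE_TSV) -> TaxonomyIndex:
    """Load a taxonomy in either dialect into a :class:`TaxonomyIndex`.

    For NCBI_TAXDUMP, `path` is the directory holding nodes.dmp/names.dmp.
    """
    if dialect is LineageDialect.SIMPLE_TSV:
        return TaxonomyIndex.from_simple_tsv(path)
    if dialect is LineageDialect.NCBI_TAXDUMP:
        return TaxonomyIndex.from_taxdump(path)
    raise ValueError(f"unknown lineage dialect: {dialect!r}")
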