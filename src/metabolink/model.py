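"""Core domain types for disease–microbe–metabolite association scoring.

The pipeline connects three controlled identifier namespaces: diseases are
MeSH descriptors, microbes are NCBI Taxonomy IDs, metabolites are PubChem
CIDs.  Disease–microbe links are directed (a genus is increased or decreased
in the disease relative to healthy controls); microbe–metabolite links are
presence-only production records at strain/species level.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional


class MetabolinkError(Exception):
    """Base class for all package errors."""


class IdentifierError(MetabolinkError):
    """A raw identifier does not conform to its namespace."""

    def __init__(self, namespace: "Namespace", value: str, reason: str = ""):
        self.namespace = namespace
        self.value = value
        msg = f"invalid {namespace.name} identifier: {value!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


class TableFormatError(MetabolinkError):
    """A table is structurally unreadable (missing columns, bad rows)."""

    def __init__(self, message: str, row_errors: Optional[list] = None):
        self.row_errors = row_errors or []
        super().__init__(message)


class TaxonomyStructureError(MetabolinkError):
    """The lineage table contains cycles or orphan parent references."""


class ResolutionError(MetabolinkError):
    """A taxid referenced by an association table is absent from the taxonomy."""


class GenerationError(MetabolinkError):
    """A synthetic-data configuration is infeasible."""


class ValidationInputError(MetabolinkError):
    """Experimental label table contains conflicting duplicate rows."""


class Namespace(enum.Enum):
    """Identifier namespaces accepted by the pipeline."""

    MESH = "mesh"
    TAXID = "taxid"
    CID = "cid"


class Direction(enum.Enum):
    """Direction of a microbial abundance change in a disease."""

    INCREASE = "increase"
    DECREASE = "decrease"

    def flipped(self) -> "Direction":
        return Direction.DECREASE if self is Direction.INCREASE else Direction.INCREASE


class ObservedDirection(enum.Enum):
    """Experimentally observed change of a metabolite in a disease."""

    UP = "up"
    DOWN = "down"

    def flipped(self) -> "ObservedDirection":
        return ObservedDirection.DOWN if self is ObservedDirection.UP else ObservedDirection.UP


class AssociationLabel(enum.Enum):
    """Interpretation of the sign of the association strength score.

    A positive score ties the metabolite to disease-enriched microbes
    (potential disease marker); a negative score ties it to disease-depleted
    microbes (candidate drug or diagnostic marker).
    """

    MARKER_LIKE = "marker_like"
    DRUG_LIKE = "drug_like"
    NEUTRAL = "neutral"


_MESH_RE = re.compile(r"^[A-Z]\d+$")


def validate_identifier(raw: str, namespace: Namespace):
    """Normalize an identifier or raise :class:`IdentifierError`.

    MeSH descriptors are upper-cased and must match letter+digits
    (e.g. ``D003424``); taxids and CIDs must parse as positive integers.

    Returns the normalized string (MESH) or int (TAXID, CID).
    """
    if not isinstance(raw, str) or not raw.strip():
        raise IdentifierError(namespace, str(raw), "empty")
    raw = raw.strip()
    if namespace is Namespace.MESH:
        norm = raw.upper()
        if not _MESH_RE.match(norm):
            raise IdentifierError(namespace, raw, "expected letter+digits descriptor")
        return norm
    try:
        value = int(raw)
    except ValueError:
        raise IdentifierError(namespace, raw, "expected integer") from None
    if value <= 0:
        raise IdentifierError(namespace, raw, "must be positive")
    return value


@dataclass(frozen=True)
class DiseaseMicrobeAssociation:
    """One directed genus-level link between a disease and a microbe."""

    disease_id: str
    microbe_taxid: int
    direction: Direction
    disease_name: Optional[str] = None
    microbe_name: Optional[str] = None
    pmid: Optional[int] = None
    method: Optional[str] = None

    def __post_init__(self):
        if not self.disease_id:
            raise ValueError("disease_id must be non-empty")
        if self.microbe_taxid <= 0:
            raise ValueError("microbe_taxid must be positive")
        if not isinstance(self.direction, Direction):
            raise ValueError(f"direction must be a Direction, got {self.direction!r}")

    @property
    def key(self) -> tuple:
        """Association identity used for deduplication (evidence excluded)."""
        return (self.disease_id, self.microbe_taxid, self.direction.value)


@dataclass(frozen=True)
class ProductionLink:
    """One strain-level microbe→metabolite production record (presence-only)."""

    microbe_taxid: int
    metabolite_id: int
    microbe_name: Optional[str] = None
    metabolite_name: Optional[str] = None

    def __post_init__(self):
        if self.microbe_taxid <= 0:
            raise ValueError("microbe_taxid must be positive")
        if self.metabolite_id <= 0:
            raise ValueError("metabolite_id (PubChem CID) must be positive")

    @property
    def key(self) -> tuple:
        return (self.microbe_taxid, self.metabolite_id)


@dataclass(frozen=True)
class ExperimentalLabel:
    """An experimentally observed disease–metabolite direction."""

    disease_id: str
    metabolite_id: int
    observed_direction: ObservedDirection
    pmid: Optional[int] = None

    @property
    def key(self) -> tuple:
        return (self.disease_id, self.metabolite_id)


@dataclass(frozen=True)
class CountQuad:
    """Strain counts underlying one disease–metabolite score.

    M / N: strains increased / decreased in the disease (after genus→strain
    propagation).  m / n: those of them that produce the metabolite.
    """

    m: int
    n: int
    M: int
    N: int

    def __post_init__(self):
        for name in ("m", "n", "M", "N"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.m > self.M:
            raise ValueError(f"m={self.m} exceeds M={self.M}")
        if self.n > self.N:
            raise ValueError(f"n={self.n} exceeds N={self.N}")


@dataclass(frozen=True)
class Thresholds:
    """Meaningfulness cut-offs, applied strictly (boundary values fail).

    A scored pair is meaningful iff |S_as| > s_as_abs_min and
    S_ac > s_ac_min.  Defaults are 0.05 and 1.
    """

    s_as_abs_min: float = 0.05
    s_ac_min: float = 1.0

    def __post_init__(self):
        if self.s_as_abs_min < 0 or self.s_ac_min < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class ScoredAssociation:
    """One scored (disease, metabolite) pair."""

    disease_id: str
    metabolite_id: int
    counts: CountQuad
    s_as: float
    s_ac: float
    meaningful: bool
    label: AssociationLabel
    metabolite_name: Optional[str] = None


@dataclass(frozen=True)
class DiseaseSummary:
    """Per-disease mean association strength over emitted pairs."""

    disease_id: str
    mean_s_as: float
    n_metabolites: int


def round_half_away(x: float, ndigits: int) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Python's built-in round() uses banker's rounding, which would print the
    confidence score 3.125 as 3.12 instead of the conventional 3.13.
    """
    q = Decimal(1).scaleb(-ndigits)
    # +0.0 normalizes -0.0 so formatted output never reads "-0.000"
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)) + 0.0


def format_score(x: float, ndigits: int) -> str:
    """Fixed-point rendering with half-away-from-zero rounding."""
    return f"{round_half_away(x, ndigits):.{ndigits}f}"


@dataclass(frozen=True)
class RowError:
    """A located problem in one data row of an input table."""

    path: str
    line: int
    message: str

    def __str__(self) -> str:
        return f"{self.path}:{self.line}: {self.message}"


@dataclass
class HarmonizationReport:
    """Audit trail of deduplication and contradiction removal."""

    records_in: int = 0
    records_out: int = 0
    duplicates_removed: int = 0
    contradictory_pairs_removed: list = field(default_factory=list)

    @property
    def contradiction_records_removed(self) -> int:
        return self.records_in - self.duplicates_removed - self.records_out
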