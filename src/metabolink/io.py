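"""Readers and writers for the canonical tab-separated tables.

Canonical layouts (UTF-8, header row):

* disease_microbe.tsv: disease_id, disease_name, microbe_taxid,
  microbe_name, direction, pmid, method
* microbe_metabolite.tsv: microbe_taxid, microbe_name, metabolite_id,
  metabolite_name
* lineage.tsv: taxid, parent_taxid, rank, name (see :mod:`.taxonomy`)
* validation.tsv: disease_id, metabolite_id, observed_direction, pmid

A `column_map` (canonical name → actual header) lets callers read tables
with renamed or reordered columns.  Direction vocabularies are fixed and
case-insensitive; unknown tokens are row-level errors, never silent skips —
curation tables are dirty and silent loss is worse than failure.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import (
    AssociationLabel,
    CountQuad,
    Direction,
    DiseaseMicrobeAssociation,
    ExperimentalLabel,
    IdentifierError,
    Namespace,
    ObservedDirection,
    ProductionLink,
    RowError,
    ScoredAssociation,
    TableFormatError,
    format_score,
    validate_identifier,
)

DIRECTION_TOKENS: Dict[str, Direction] = {
    "increase": Direction.INCREASE,
    "increased": Direction.INCREASE,
    "up": Direction.INCREASE,
    "decrease": Direction.DECREASE,
    "decreased": Direction.DECREASE,
    "down": Direction.DECREASE,
}

OBSERVED_TOKENS: Dict[str, ObservedDirection] = {
    "up": ObservedDirection.UP,
    "increase": ObservedDirection.UP,
    "increased": ObservedDirection.UP,
    "down": ObservedDirection.DOWN,
    "decrease": ObservedDirection.DOWN,
    "decreased": ObservedDirection.DOWN,
}

SCORED_COLUMNS = [
    "disease_id",
    "metabolite_id",
    "m",
    "n",
    "M",
    "N",
    "s_as",
    "s_ac",
    "meaningful",
    "label",
]


def _load_frame(path, required: Sequence[str], column_map: Optional[Dict[str, str]]):
    column_map = column_map or {}
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file (no header row)") from None
    rename = {actual: canon for canon, actual in column_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    return df


def _finish(path, records, errors, on_error):
    if errors and on_error == "raise":
        detail = "; ".join(str(e) for e in errors[:10])
        raise TableFormatError(
            f"{path}: {len(errors)} malformed row(s): {detail}", row_errors=errors
        )
    if on_error == "collect":
        return records, errors
    return records


def read_disease_microbe_table(
    path,
    column_map: Optional[Dict[str, str]] = None,
    on_error: str = "raise",
):
    """Read directed genus-level disease–microbe associations.

    With ``on_error="collect"`` returns ``(records, row_errors)`` instead of
    raising, so every data row is accounted for as exactly one record or one
    located error.
    """
    df = _load_frame(path, ["disease_id", "microbe_taxid", "direction"], column_map)
    records: List[DiseaseMicrobeAssociation] = []
    errors: List[RowError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            disease_id = validate_identifier(row.disease_id, Namespace.MESH)
            taxid = validate_identifier(row.microbe_taxid, Namespace.TAXID)
            token = row.direction.strip().lower()
            if token not in DIRECTION_TOKENS:
                raise ValueError(f"unknown direction token {row.direction!r}")
            records.append(
                DiseaseMicrobeAssociation(
                    disease_id=disease_id,
                    microbe_taxid=taxid,
                    direction=DIRECTION_TOKENS[token],
                    disease_name=getattr(row, "disease_name", None) or None,
                    microbe_name=getattr(row, "microbe_name", None) or None,
                    pmid=_opt_int(getattr(row, "pmid", "")),
                    method=getattr(row, "method", None) or None,
                )
            )
        except (IdentifierError, ValueError) as exc:
            errors.append(RowError(str(path), line, str(exc)))
    return _finish(path, records, errors, on_error)


def read_microbe_metabolite_table(
    path,
    column_map: Optional[Dict[str, str]] = None,
    on_error: str = "raise",
):
    """Read strain-level microbe→metabolite production links.

    Duplicate (taxid, cid) rows are kept; harmonization removes them.
    """
    df = _load_frame(path, ["microbe_taxid", "metabolite_id"], column_map)
    records: List[ProductionLink] = []
    errors: List[RowError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            taxid = validate_identifier(row.microbe_taxid, Namespace.TAXID)
            cid = validate_identifier(row.metabolite_id, Namespace.CID)
            records.append(
                ProductionLink(
                    microbe_taxid=taxid,
                    metabolite_id=cid,
                    microbe_name=getattr(row, "microbe_name", None) or None,
                    metabolite_name=getattr(row, "metabolite_name", None) or None,
                )
            )
        except (IdentifierError, ValueError) as exc:
            errors.append(RowError(str(path), line, str(exc)))
    return _finish(path, records, errors, on_error)


def read_validation_table(
    path,
    column_map: Optional[Dict[str, str]] = None,
    on_error: str = "raise",
):
    """Read experimentally observed disease–metabolite directions."""
    df = _load_frame(
        path, ["disease_id", "metabolite_id", "observed_direction"], column_map
    )
    records: List[ExperimentalLabel] = []
    errors: List[RowError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            disease_id = validate_identifier(row.disease_id, Namespace.MESH)
            cid = validate_identifier(row.metabolite_id, Namespace.CID)
            token = row.observed_direction.strip().lower()
            if token not in OBSERVED_TOKENS:
                raise ValueError(
                    f"unknown observed direction token {row.observed_direction!r}"
                )
            records.append(
                ExperimentalLabel(
                    disease_id=disease_id,
                    metabolite_id=cid,
                    observed_direction=OBSERVED_TOKENS[token],
                    pmid=_opt_int(getattr(row, "pmid", "")),
                )
            )
        except (IdentifierError, ValueError) as exc:
            errors.append(RowError(str(path), line, str(exc)))
    return _finish(path, records, errors, on_error)


def _opt_int(value) -> Optional[int]:
    if value is None:
        return None
    value = str(value).strip()
    if not value:
        return None
    return int(value)


def write_disease_microbe_table(records, path) -> None:
    df = pd.DataFrame(
        [
            {
                "disease_id": r.disease_id,
                "disease_name": r.disease_name or "",
                "microbe_taxid": r.microbe_taxid,
                "microbe_name": r.microbe_name or "",
                "direction": r.direction.value,
                "pmid": "" if r.pmid is None else r.pmid,
                "method": r.method or "",
            }
            for r in records
        ],
        columns=[
            "disease_id",
            "disease_name",
            "microbe_taxid",
            "microbe_name",
            "direction",
            "pmid",
            "method",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def write_microbe_metabolite_table(records, path) -> None:
    df = pd.DataFrame(
        [
            {
                "microbe_taxid": r.microbe_taxid,
                "microbe_name": r.microbe_name or "",
                "metabolite_id": r.metabolite_id,
                "metabolite_name": r.metabolite_name or "",
            }
            for r in records
        ],
        columns=["microbe_taxid", "microbe_name", "metabolite_id", "metabolite_name"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_validation_table(records, path) -> None:
    df = pd.DataFrame(
        [
            {
                "disease_id": r.disease_id,
                "metabolite_id": r.metabolite_id,
                "observed_direction": r.observed_direction.value,
                "pmid": "" if r.pmid is None else r.pmid,
            }
            for r in records
        ],
        columns=["disease_id", "metabolite_id", "observed_direction", "pmid"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_scored_table(records, path, full_precision: bool = False) -> None:
    """Write scored associations as TSV.

    S_as prints to 3 decimals and S_ac to 2 (half away from zero, matching
    the conventional rendering of e.g. 3.125 as "3.13").  With
    ``full_precision=True`` the unrounded values are appended as an extra
    column pair.
    """
    columns = list(SCORED_COLUMNS)
    if full_precision:
        columns += ["s_as_exact", "s_ac_exact"]
    rows = []
    for r in records:
        row = {
            "disease_id": r.disease_id,
            "metabolite_id": r.metabolite_id,
            "m": r.counts.m,
            "n": r.counts.n,
            "M": r.counts.M,
            "N": r.counts.N,
            "s_as": format_score(r.s_as, 3),
            "s_ac": format_score(r.s_ac, 2),
            "meaningful": str(r.meaningful).lower(),
            "label": r.label.value,
        }
        if full_precision:
            row["s_as_exact"] = repr(r.s_as)
            row["s_ac_exact"] = repr(r.s_ac)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_scored_table(path) -> List[ScoredAssociation]:
    """Read back a table written by :func:`write_scored_table`.

    Scores come back at printed precision unless the exact columns are
    present, in which case those are used.
    """
    df = _load_frame(path, SCORED_COLUMNS, None)
    records = []
    for row in df.itertuples(index=False):
        s_as = float(getattr(row, "s_as_exact", row.s_as))
        s_ac = float(getattr(row, "s_ac_exact", row.s_ac))
        records.append(
            ScoredAssociation(
                disease_id=row.disease_id,
                metabolite_id=int(row.metabolite_id),
                counts=CountQuad(int(row.m), int(row.n), int(row.M), int(row.N)),
                s_as=s_as,
                s_ac=s_ac,
                meaningful=row.meaningful.strip().lower() == "true",
                label=AssociationLabel(row.label),
            )
        )
    return records


def write_summary_table(summaries, path) -> None:
    df = pd.DataFrame(
        [
            {
                "disease_id": s.disease_id,
                "mean_s_as": format_score(s.mean_s_as, 4),
                "n_metabolites": s.n_metabolites,
            }
            for s in summaries
        ],
        columns=["disease_id", "mean_s_as", "n_metabolites"],
    )
    df.to_csv(path, sep="\t", index=False)
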