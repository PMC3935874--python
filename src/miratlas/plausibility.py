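"""Five-category plausibility classification of reported blood biomarkers.

A circulating microRNA reported as a disease biomarker is scored against
the cell atlas and a disease → involved-cell-types map:

* **likely** — expressed in a disease-relevant cell type without being
  ubiquitous (some cellular exclusivity);
* **questionable** — not expressed at a moderate level in any profiled
  cell type (often carrier-strand / minor-arm microRNAs reported as noise);
* **ubiquitous** — called expressed in 7 or more cell types, hence too
  widespread to mark any one disease;
* **unlikely** — expressed, but only in cells unrelated to the disease;
* **unknown** — the name does not resolve, or the atlas has no data.

PBMC studies measure cells directly, so there the only question is whether
the microRNA is leukocyte-expressed: leukocyte expression outranks the
ubiquity rule in that compartment.  (The source framework carries this
tension explicitly: a microRNA ubiquitous in cell-free fluids can still be
a fair PBMC biomarker.)
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .atlas import CellAtlas, expressed_cells
from .nomenclature import NomenclatureKey, UnknownMirnaError, harmonize

__all__ = [
    "COMPARTMENTS",
    "DIRECTIONS",
    "CATEGORIES",
    "BiomarkerReport",
    "DiseaseCellMap",
    "PlausibilityCall",
    "classify",
    "classify_table",
    "read_reports",
]

logger = logging.getLogger(__name__)

COMPARTMENTS = ("serum", "plasma", "PBMC", "blood_NOS")
DIRECTIONS = ("up", "down", "mixed")
CATEGORIES = ("likely", "questionable", "ubiquitous", "unlikely", "unknown")

DEFAULT_UBIQUITY_THRESHOLD = 7


@dataclass(frozen=True)
class BiomarkerReport:
    """One microRNA reported as a biomarker by one study."""

    study_id: str
    disease: str
    compartment: str
    mirna_name: str
    direction: str
    normalization_method: str = ""
    journal_impact_factor: float | None = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment {self.compartment!r} not in {COMPARTMENTS}"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction {self.direction!r} not in {DIRECTIONS}")


@dataclass
class DiseaseCellMap:
    """Disease → atlas cell types involved, plus tissue-level overrides.

    The mapping is curated input (clinical judgement), consumed as config.
    ``tissue_overrides`` lets a disease draw likely-evidence from
    tissue-level expression carried in atlas metadata (e.g. placenta for
    pre-eclampsia) when the relevant cell types are not profiled.
    """

    cells: dict[str, frozenset[str]]
    tissue_overrides: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, disease: str) -> bool:
        return disease in self.cells or disease in self.tissue_overrides

    def cells_for(self, disease: str) -> frozenset[str]:
        if disease not in self:
            raise KeyError(
                f"disease {disease!r} is not in the disease→cell-type map; "
                "extend the configuration with the cell types involved"
            )
        return self.cells.get(disease, frozenset())

    def tissues_for(self, disease: str) -> frozenset[str]:
        return self.tissue_overrides.get(disease, frozenset())

    def validate_against(self, atlas: CellAtlas) -> None:
        known = set(atlas.cell_types)
        for disease, cc in self.cells.items():
            stray = cc - known
            if stray:
                raise ValueError(
                    f"disease {disease!r} references cell types absent from "
                    f"the atlas: {sorted(stray)}"
                )


@dataclass(frozen=True)
class PlausibilityCall:
    """A category plus the evidence that produced it (recomputable)."""

    category: str
    expressed_cell_count: int | None
    expressed_cells: frozenset[str] | None
    disease_overlap: frozenset[str]
    rationale_code: str
    accession: str | None = None
    canonical_name: str | None = None


def classify(
    report: BiomarkerReport,
    atlas: CellAtlas,
    disease_map: DiseaseCellMap,
    key: NomenclatureKey,
    ubiquity_threshold: int = DEFAULT_UBIQUITY_THRESHOLD,
    leukocyte_cells: Iterable[str] | None = None,
) -> PlausibilityCall:
    """Classify one biomarker report.

    Decision order: (1) unresolvable name or no atlas data → unknown;
    (2) expressed nowhere → questionable; (3) PBMC compartment → likely iff
    leukocyte-expressed, else unlikely; (4) expressed in >= 7 cell types →
    ubiquitous; (5) expressed in a disease-mapped cell type (or
    tissue-override evidence) → likely; (6) otherwise unlikely.

    ``leukocyte_cells`` defaults to the atlas's hematopoietic labels.
    A disease absent from the map is an error (extend the config).
    """
    if report.disease not in disease_map:
        disease_map.cells_for(report.disease)  # raises with guidance

    try:
        mid = harmonize(report.mirna_name, key)
    except UnknownMirnaError:
        return PlausibilityCall(
            "unknown", None, None, frozenset(), "unresolvable_name"
        )

    hit = expressed_cells(atlas, mid)
    if hit.no_data:
        return PlausibilityCall(
            "unknown", None, None, frozenset(), "no_atlas_data",
            mid.accession, mid.canonical_name,
        )
    cells = hit.cells
    count = hit.count
    mapped = disease_map.cells_for(report.disease)
    overlap = frozenset(cells & mapped)

    if count == 0:
        return PlausibilityCall(
            "questionable", 0, cells, overlap, "no_expression",
            mid.accession, mid.canonical_name,
        )
    if report.compartment == "PBMC":
        leuko = frozenset(
            map(str, leukocyte_cells)
        ) if leukocyte_cells is not None else atlas.hematopoietic
        leuko_hit = frozenset(cells & leuko)
        if leuko_hit:
            return PlausibilityCall(
                "likely", count, cells, leuko_hit, "pbmc_leukocyte_expression",
                mid.accession, mid.canonical_name,
            )
        return PlausibilityCall(
            "unlikely", count, cells, overlap, "pbmc_not_leukocyte",
            mid.accession, mid.canonical_name,
        )
    if count >= ubiquity_threshold:
        return PlausibilityCall(
            "ubiquitous", count, cells, overlap, "ubiquitous_expression",
            mid.accession, mid.canonical_name,
        )
    if overlap:
        return PlausibilityCall(
            "likely", count, cells, overlap, "disease_cell_expression",
            mid.accession, mid.canonical_name,
        )
    # Tissue-level override: disease maps to a tissue carried in atlas
    # metadata and the microRNA is on that tissue's expressed list.
    for tissue in disease_map.tissues_for(report.disease):
        if mid.accession in atlas.tissue_expression.get(tissue, frozenset()):
            return PlausibilityCall(
                "likely", count, cells, frozenset({tissue}),
                "tissue_override_expression", mid.accession, mid.canonical_name,
            )
    return PlausibilityCall(
        "unlikely", count, cells, overlap, "no_disease_cell_expression",
        mid.accession, mid.canonical_name,
    )


def classify_table(
    reports: Sequence[BiomarkerReport],
    atlas: CellAtlas,
    disease_map: DiseaseCellMap,
    key: NomenclatureKey,
    **kwargs,
) -> pd.DataFrame:
    """Classify every report; one row per report, order preserved.

    Unresolvable names become category "unknown" (the classifier handles
    that internally); any other per-row failure is re-raised annotated with
    the row index.  A summary of category counts is logged.
    """
    rows = []
    for i, report in enumerate(reports):
        try:
            call = classify(report, atlas, disease_map, key, **kwargs)
        except Exception as exc:
            raise type(exc)(f"report row {i}: {exc}") from exc
        rows.append(
            {
                "study_id": report.study_id,
                "disease": report.disease,
                "compartment": report.compartment,
                "mirna_name": report.mirna_name,
                "accession": call.accession,
                "canonical_name": call.canonical_name,
                "direction": report.direction,
                "category": call.category,
                "expressed_cell_count": call.expressed_cell_count,
                "expressed_cells": ";".join(sorted(call.expressed_cells))
                if call.expressed_cells is not None
                else None,
                "disease_overlap": ";".join(sorted(call.disease_overlap)),
                "rationale_code": call.rationale_code,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "study_id", "disease", "compartment", "mirna_name", "accession",
            "canonical_name", "direction", "category", "expressed_cell_count",
            "expressed_cells", "disease_overlap", "rationale_code",
        ],
    )
    if len(out):
        logger.info("classify_table: %s", dict(Counter(out["category"])))
    return out


def read_reports(path: str | Path, sep: str = "\t") -> list[BiomarkerReport]:
    """Read a biomarker report table (TSV by default).

    Required columns: ``study_id``, ``disease``, ``compartment``, ``mirna``,
    ``direction``; optional ``normalization`` and ``impact_factor``.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["study_id", "disease", "compartment", "mirna", "direction"]
    lacking = [c for c in required if c not in df.columns]
    if lacking:
        raise ValueError(f"report table lacks required columns {lacking}")
    out = []
    for _, row in df.iterrows():
        impact = row.get("impact_factor")
        out.append(
            BiomarkerReport(
                study_id=str(row["study_id"]),
                disease=str(row["disease"]),
                compartment=str(row["compartment"]),
                mirna_name=str(row["mirna"]),
                direction=str(row["direction"]),
                normalization_method=str(row.get("normalization") or ""),
                journal_impact_factor=float(impact)
                if impact not in (None, "",) and not pd.isna(impact)
                else None,
            )
        )
    return out
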