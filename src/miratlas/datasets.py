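"""Built-in demonstration inputs: a synthetic cell atlas and study tables.

The published per-cell expression matrix and the curated 104-study
biomarker grid are spreadsheet downloads; this module ships **synthetic
stand-ins** constructed to encode the documented facts about them, so the
whole pipeline is runnable and testable offline:

* :func:`demo_cell_atlas` — an 18-cell-type atlas whose expression pattern
  encodes well-established cell specificities (miR-122 hepatocyte-only,
  miR-451a red-cell-only, miR-223 myeloid, miR-21/miR-16 ubiquitous,
  miR-29a in 16 of 18 cell types, carrier strands below the noise floor);
* :func:`tuberculosis_reports` — the ten biomarker reports of the three
  tuberculosis studies used as the classifier's worked example;
* :func:`synthetic_study_grid` — a deterministic 104-study × 192-microRNA
  classified report table with the headline structure of the curated
  literature corpus (report/merged category tallies, multi-manuscript and
  promiscuous microRNAs, a cardiac subset, within-disease replication and
  direction conflicts), for exercising the audit machinery at full scale.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .atlas import CellAtlas, build_atlas
from .ingest import SampleMatrix
from .nomenclature import NomenclatureKey, build_key
from .plausibility import BiomarkerReport, DiseaseCellMap

__all__ = [
    "LEUKOCYTES",
    "demo_nomenclature_key",
    "demo_cell_atlas",
    "demo_disease_map",
    "tuberculosis_reports",
    "synthetic_study_grid",
    "grid_nomenclature_key",
]

HEMATOPOIETIC = (
    "B cell", "T cell", "NK cell", "monocyte", "neutrophil",
    "dendritic cell", "platelet", "red blood cell",
)
NON_HEMATOPOIETIC = (
    "endothelial cell", "fibroblast", "hepatocyte", "skeletal myocyte",
    "smooth muscle cell", "adipocyte", "ductal cell", "acinar cell",
    "keratinocyte", "melanocyte",
)
CELL_TYPES = HEMATOPOIETIC + NON_HEMATOPOIETIC

#: Mononuclear/granulocytic white cells: the compartment PBMC assays sample.
#: Red blood cells and platelets are hematopoietic but not leukocytes.
LEUKOCYTES = frozenset(
    {"B cell", "T cell", "NK cell", "monocyte", "neutrophil", "dendritic cell"}
)

_ALIAS_ROWS = [
    ("MIMAT0000646", "hsa-miR-155;hsa-miR-155-5p"),
    ("MIMAT0004658", "hsa-miR-155*;hsa-miR-155-3p"),
    ("MIMAT0000280", "hsa-miR-223;hsa-miR-223-3p"),
    ("MIMAT0001631", "hsa-miR-451;hsa-miR-451a"),
    ("MIMAT0000436", "hsa-miR-144;hsa-miR-144-3p"),
    ("MIMAT0001341", "hsa-miR-424;hsa-miR-424-5p"),
    ("MIMAT0000710", "hsa-miR-365;hsa-miR-365-3p;hsa-miR-365a-3p"),
    ("MIMAT0000076", "hsa-miR-21;hsa-miR-21-5p"),
    ("MIMAT0004494", "hsa-miR-21*;hsa-miR-21-3p"),
    ("MIMAT0004509", "hsa-miR-93*;hsa-miR-93-3p"),
    ("MIMAT0000086", "hsa-miR-29a;hsa-miR-29a-3p"),
    ("MIMAT0000421", "hsa-miR-122;hsa-miR-122-5p"),
    ("MIMAT0000069", "hsa-miR-16;hsa-miR-16-5p"),
    ("MIMAT0000445", "hsa-miR-126;hsa-miR-126-3p"),
    ("MIMAT0000241", "hsa-miR-208a;hsa-miR-208a-3p"),
    ("MIMAT0000416", "hsa-miR-1;hsa-miR-1-3p"),
    ("MIMAT0000427", "hsa-miR-133a;hsa-miR-133a-3p"),
    ("MIMAT0000063", "hsa-let-7b;hsa-let-7b-5p"),
    ("MIMAT0004482", "hsa-let-7b*;hsa-let-7b-3p"),
    ("MIMAT0002852", "hsa-miR-517a;hsa-miR-517a-3p"),
]


def demo_nomenclature_key() -> NomenclatureKey:
    """Key over the microRNAs appearing in the demonstration data."""
    return build_key(_ALIAS_ROWS)


def demo_cell_atlas(threshold: float = 8.0) -> CellAtlas:
    """Synthetic 18-cell-type atlas encoding known cell specificities.

    One summary value per (cell type, microRNA) on the log2 scale in the
    observed 4.8–12.8 range; values below 7.0 are array noise.  This is a
    constructed stand-in for a normalized multi-study expression table,
    not measured data.
    """
    base = {
        # accession: (baseline, {cell: value})
        "MIMAT0000646": (5.6, {  # miR-155-5p: leukocytes + broad (12 cells)
            **{c: 10.5 for c in LEUKOCYTES},
            "platelet": 8.6, "endothelial cell": 9.1, "fibroblast": 8.8,
            "keratinocyte": 8.4, "smooth muscle cell": 8.3, "adipocyte": 8.2,
        }),
        "MIMAT0004658": (5.2, {}),                    # miR-155-3p: noise
        "MIMAT0000280": (5.5, {                       # miR-223-3p: myeloid
            "monocyte": 11.2, "neutrophil": 11.8, "platelet": 9.0,
        }),
        "MIMAT0001631": (5.0, {"red blood cell": 12.5}),   # miR-451a
        "MIMAT0000436": (5.1, {"red blood cell": 9.8}),    # miR-144-3p
        "MIMAT0001341": (5.3, {"endothelial cell": 9.2}),  # miR-424-5p
        "MIMAT0000710": (5.4, {                       # miR-365a-3p
            "fibroblast": 9.0, "keratinocyte": 8.4,
        }),
        "MIMAT0000076": (11.4, {}),                   # miR-21-5p: everywhere
        "MIMAT0004494": (5.4, {}),                    # miR-21-3p: noise
        "MIMAT0004509": (5.6, {}),                    # miR-93-3p: noise
        "MIMAT0000086": (9.7, {                       # miR-29a-3p: 16/18
            "platelet": 6.4, "red blood cell": 6.0,
        }),
        "MIMAT0000421": (5.2, {"hepatocyte": 12.7}),  # miR-122-5p
        "MIMAT0000069": (10.6, {}),                   # miR-16-5p: everywhere
        "MIMAT0000445": (5.9, {                       # miR-126-3p
            "endothelial cell": 12.0, "monocyte": 8.5,
        }),
        "MIMAT0000241": (5.0, {}),                    # miR-208a-3p: no signal
        "MIMAT0000416": (5.1, {"skeletal myocyte": 12.0}),     # miR-1-3p
        "MIMAT0000427": (5.2, {                       # miR-133a-3p
            "skeletal myocyte": 11.5, "smooth muscle cell": 8.2,
        }),
        "MIMAT0000063": (10.1, {}),                   # let-7b-5p: everywhere
        "MIMAT0004482": (5.8, {}),                    # let-7b-3p: noise
    }
    values = pd.DataFrame(
        {acc: [spec[1].get(c, spec[0]) for c in CELL_TYPES]
         for acc, spec in base.items()},
        index=list(CELL_TYPES),
        dtype=float,
    )
    samples = values.copy()
    samples.index = [f"{c}__s1" for c in CELL_TYPES]
    meta = pd.DataFrame(
        {"label": list(CELL_TYPES), "platform_version": "demo",
         "batch_id": "demo"},
        index=samples.index,
    )
    return build_atlas(
        SampleMatrix(samples, meta),
        threshold=threshold,
        hematopoietic=HEMATOPOIETIC,
        contamination={
            "ductal cell": "carries red-cell and endothelial signal "
            "(crude microdissection)",
            "acinar cell": "carries red-cell and endothelial signal "
            "(crude microdissection)",
        },
        tissue_expression={"placenta": ["MIMAT0002852"]},  # miR-517a family
    )


def demo_disease_map() -> DiseaseCellMap:
    return DiseaseCellMap(
        cells={
            "tuberculosis": frozenset(LEUKOCYTES),
            "myocardial infarction": frozenset(
                {"skeletal myocyte", "smooth muscle cell", "endothelial cell"}
            ),
            "hepatitis": frozenset({"hepatocyte"}),
            "sepsis": frozenset(LEUKOCYTES | {"endothelial cell"}),
            "pre-eclampsia": frozenset({"endothelial cell"}),
        },
        tissue_overrides={"pre-eclampsia": frozenset({"placenta"})},
    )


def tuberculosis_reports() -> list[BiomarkerReport]:
    """The ten biomarker reports of the three-study tuberculosis example.

    Two PBMC studies and one serum study; the split of microRNAs between
    the two PBMC studies does not affect any tally.
    """

    def r(study, compartment, name, direction="up"):
        return BiomarkerReport(
            study_id=study, disease="tuberculosis", compartment=compartment,
            mirna_name=name, direction=direction,
        )

    return [
        r("TB-PBMC-1", "PBMC", "miR-155-5p"),
        r("TB-PBMC-1", "PBMC", "miR-155-3p"),
        r("TB-PBMC-1", "PBMC", "miR-424-5p"),
        r("TB-PBMC-1", "PBMC", "miR-451a"),
        r("TB-PBMC-2", "PBMC", "miR-223-3p"),
        r("TB-PBMC-2", "PBMC", "miR-21-3p"),
        r("TB-PBMC-2", "PBMC", "miR-144-3p"),
        r("TB-PBMC-2", "PBMC", "miR-365-3p"),
        r("TB-serum-3", "serum", "miR-29a-3p"),
        r("TB-serum-3", "serum", "miR-93-3p"),
    ]


# --------------------------------------------------------------------------
# Synthetic full-scale study grid (stand-in for the curated 104-study corpus)
# --------------------------------------------------------------------------

_CARDIAC_ELIGIBLE = [
    ("myocardial_infarction", 10),
    ("heart_failure", 5),
    ("coronary_artery_disease", 5),
    ("acute_coronary_syndrome", 4),
]
_OTHER_ELIGIBLE = [
    ("hepatitis_c", 6), ("sepsis", 5), ("multiple_sclerosis", 4),
    ("lupus", 4), ("diabetes", 4), ("rheumatoid_arthritis", 3),
    ("hepatitis_b", 3), ("pre_eclampsia", 3), ("crohns_disease", 2),
    ("osteoarthritis", 2), ("psoriasis", 2),
]
_CARDIAC_SINGLE = [
    "atrial_fibrillation", "aortic_stenosis", "cardiac_arrest",
    "hypertension", "viral_myocarditis",
]
_N_OTHER_SINGLE = 37

# Multi-study (accession, disease) pair plan: (disease, category, n_studies,
# opposite?).  Sizes are bounded by the disease's study count; replicated
# pairs are concordant, opposite pairs split up/down across two studies.
_MULTI_PAIRS = [
    # cardiac
    ("myocardial_infarction", "likely", 9, False),
    ("myocardial_infarction", "likely", 4, False),
    ("myocardial_infarction", "likely", 4, False),
    ("myocardial_infarction", "ubiquitous", 5, False),
    ("myocardial_infarction", "questionable", 2, False),
    ("myocardial_infarction", "questionable", 2, True),
    ("heart_failure", "likely", 5, False),
    ("heart_failure", "ubiquitous", 4, False),
    ("coronary_artery_disease", "likely", 5, False),
    ("coronary_artery_disease", "ubiquitous", 4, False),
    ("coronary_artery_disease", "unlikely", 2, True),
    ("acute_coronary_syndrome", "likely", 4, False),
    ("acute_coronary_syndrome", "ubiquitous", 3, False),
    # non-cardiac
    ("hepatitis_c", "likely", 6, False),
    ("sepsis", "likely", 5, False),
    ("sepsis", "ubiquitous", 5, False),
    ("sepsis", "ubiquitous", 5, False),
    ("multiple_sclerosis", "likely", 4, False),
    ("multiple_sclerosis", "ubiquitous", 4, False),
    ("lupus", "likely", 4, False),
    ("lupus", "ubiquitous", 3, False),
    ("diabetes", "likely", 4, False),
    ("rheumatoid_arthritis", "questionable", 2, False),
    ("rheumatoid_arthritis", "questionable", 2, True),
    ("hepatitis_b", "questionable", 2, True),
    ("hepatitis_b", "questionable", 2, True),
    ("pre_eclampsia", "questionable", 2, True),
    ("crohns_disease", "questionable", 2, True),
    ("osteoarthritis", "unlikely", 2, True),
]

_COMPARTMENT_CYCLE = ("serum", "plasma", "serum", "plasma", "PBMC")


class _GridBuilder:
    """Deterministic constructor for the synthetic study grid."""

    def __init__(self) -> None:
        self.eligible = dict(_CARDIAC_ELIGIBLE + _OTHER_ELIGIBLE)
        self.single_cardiac = list(_CARDIAC_SINGLE)
        self.single_other = [f"cond_{i:02d}" for i in range(_N_OTHER_SINGLE)]
        self.other_eligible = [d for d, _ in _OTHER_ELIGIBLE]
        self.studies: dict[str, list[str]] = {}
        self.compartment: dict[str, str] = {}
        comp = itertools.cycle(_COMPARTMENT_CYCLE)
        for disease, n in self.eligible.items():
            self.studies[disease] = [f"{disease}_st{j+1}" for j in range(n)]
        for disease in self.single_cardiac + self.single_other:
            self.studies[disease] = [f"{disease}_st1"]
        for disease in self.studies:
            for sid in self.studies[disease]:
                self.compartment[sid] = next(comp)
        self.cursor = {d: 0 for d in self.studies}
        self.rows: list[dict] = []
        self.n_acc = 0
        self.names: dict[str, str] = {}
        # rotating pickers for single-report placement
        self._rot_other_eligible = itertools.cycle(self.other_eligible)
        self._rot_single_other = itertools.cycle(self.single_other)
        self._rot_cardiac_eligible = itertools.cycle(
            [d for d, _ in _CARDIAC_ELIGIBLE]
        )
        self._rot_cardiac_single = itertools.cycle(self.single_cardiac)
        self._dir = itertools.cycle(("up", "up", "down"))

    def new_accession(self) -> str:
        acc = f"MIMATX{self.n_acc:04d}"
        self.names[acc] = f"hsa-miR-x{self.n_acc}"
        self.n_acc += 1
        return acc

    def next_studies(self, disease: str, n: int) -> list[str]:
        pool = self.studies[disease]
        if n > len(pool):
            raise ValueError(f"{disease} has only {len(pool)} studies, need {n}")
        start = self.cursor[disease]
        picked = [pool[(start + j) % len(pool)] for j in range(n)]
        self.cursor[disease] = (start + n) % len(pool)
        return picked

    def add(self, acc: str, disease: str, study: str, category: str,
            direction: str) -> None:
        self.rows.append(
            {
                "study_id": study,
                "disease": disease,
                "compartment": self.compartment[study],
                "mirna_name": self.names[acc],
                "accession": acc,
                "direction": direction,
                "category": category,
            }
        )

    def add_single(self, acc: str, disease: str, category: str) -> None:
        study = self.next_studies(disease, 1)[0]
        self.add(acc, disease, study, category, next(self._dir))

    def distinct(self, rot: "itertools.cycle", n: int, pool_size: int) -> list[str]:
        if n > pool_size:
            raise ValueError("not enough distinct diseases")
        out: list[str] = []
        while len(out) < n:
            d = next(rot)
            if d not in out:
                out.append(d)
        return out

    def build(self) -> pd.DataFrame:
        # 1. multi-study pairs (replication / direction-conflict structure)
        for disease, category, size, opposite in _MULTI_PAIRS:
            acc = self.new_accession()
            for j, study in enumerate(self.next_studies(disease, size)):
                direction = "down" if (opposite and j == 1) else "up"
                self.add(acc, disease, study, category, direction)

        # 2. promiscuous microRNAs: 6 accessions × 13 diseases, one single
        #    report each (2 cardiac + 6 other-eligible + 5 other-single)
        for _ in range(6):
            acc = self.new_accession()
            diseases = (
                self.distinct(self._rot_cardiac_eligible, 1, 4)
                + self.distinct(self._rot_cardiac_single, 1, 5)
                + self.distinct(self._rot_other_eligible, 6, 11)
                + self.distinct(self._rot_single_other, 5, _N_OTHER_SINGLE)
            )
            for d in diseases:
                self.add_single(acc, d, "ubiquitous")

        # 3. accessions reported for a handful of diseases (multi-manuscript)
        #    14 × 2 diseases: 7 likely, 7 questionable
        for i in range(14):
            acc = self.new_accession()
            category = "likely" if i < 7 else "questionable"
            for d in (
                self.distinct(self._rot_other_eligible, 1, 11)
                + self.distinct(self._rot_single_other, 1, _N_OTHER_SINGLE)
            ):
                self.add_single(acc, d, category)
        #    20 × 4 diseases: 9 likely, 4 questionable, 7 ubiquitous;
        #    the first 10 carry 2 cardiac pairs (cardiac-subset structure)
        cats_4d = ["likely"] * 9 + ["questionable"] * 4 + ["ubiquitous"] * 7
        for i, category in enumerate(cats_4d):
            acc = self.new_accession()
            if i < 10:
                diseases = (
                    self.distinct(self._rot_cardiac_eligible, 1, 4)
                    + self.distinct(self._rot_cardiac_single, 1, 5)
                    + self.distinct(self._rot_other_eligible, 1, 11)
                    + self.distinct(self._rot_single_other, 1, _N_OTHER_SINGLE)
                )
            else:
                diseases = (
                    self.distinct(self._rot_other_eligible, 2, 11)
                    + self.distinct(self._rot_single_other, 2, _N_OTHER_SINGLE)
                )
            for d in diseases:
                self.add_single(acc, d, category)

        # 4. single-report accessions: 123 total; the first two carry the
        #    remaining cardiac reports
        singles = (
            ["likely"] * 35 + ["questionable"] * 47 + ["unlikely"] * 33
            + ["unknown"] * 8
        )
        # placement quotas: eligible-non-cardiac 54, single-non-cardiac 67,
        # one eligible-cardiac, one single-cardiac
        placements = (
            [("cardiac_eligible", 1)] + [("cardiac_single", 1)]
            + [("other_eligible", 1)] * 54 + [("other_single", 1)] * 67
        )
        assert len(placements) == len(singles)
        for category, (where, _) in zip(singles, placements):
            acc = self.new_accession()
            if where == "cardiac_eligible":
                d = self.distinct(self._rot_cardiac_eligible, 1, 4)[0]
            elif where == "cardiac_single":
                d = self.distinct(self._rot_cardiac_single, 1, 5)[0]
            elif where == "other_eligible":
                d = self.distinct(self._rot_other_eligible, 1, 11)[0]
            else:
                d = self.distinct(self._rot_single_other, 1, _N_OTHER_SINGLE)[0]
            self.add_single(acc, d, category)

        df = pd.DataFrame(self.rows)
        covered = set(df["study_id"])
        empty = [s for ss in self.studies.values() for s in ss if s not in covered]
        if empty:
            raise AssertionError(f"studies without reports: {empty}")
        return df


def synthetic_study_grid() -> pd.DataFrame:
    """Long classified-calls table for the synthetic 104-study corpus.

    Columns: study_id, disease, compartment, mirna_name, accession,
    direction, category — the shape ``read_study_grid`` produces and every
    audit operation consumes.  Fully deterministic.
    """
    return _GridBuilder().build()


def grid_nomenclature_key() -> NomenclatureKey:
    """Key covering the synthetic study grid's microRNA names."""
    b = _GridBuilder()
    df = b.build()
    return build_key([(acc, b.names[acc]) for acc in sorted(set(df["accession"]))])


def cardiac_diseases() -> frozenset[str]:
    """Disease labels of the synthetic grid's cardiac subset."""
    return frozenset(d for d, _ in _CARDIAC_ELIGIBLE) | frozenset(_CARDIAC_SINGLE)
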