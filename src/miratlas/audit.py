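"""Forest-level auditing of biomarker reports across studies.

Individual studies report microRNA biomarkers one disease at a time; the
global picture — how often the same microRNA is claimed for unrelated
diseases, how often independent studies of one disease agree — is what
decides whether a marker is usable.  This module de-duplicates report
tables onto unique (microRNA, disease) pairs, tallies plausibility
categories at the report and merged level, flags promiscuous microRNAs
(claimed "specific" for many diseases), scores within-disease replication
and direction conflicts, classes each study's normalization strategy as
poor or acceptable, and wraps the χ²/Welch-t comparisons used to relate
biomarker quality to study metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import NomenclatureKey, UnknownMirnaError, harmonize
from .plausibility import BiomarkerReport, CATEGORIES

__all__ = [
    "AuditSummary",
    "dedupe_and_count",
    "replication_stats",
    "tally_categories",
    "normalization_quality",
    "chi_square_2x2",
    "welch_t",
    "read_study_grid",
    "write_study_grid",
]

logger = logging.getLogger(__name__)

#: Merged-level conflict resolution: when one (microRNA, disease) pair got
#: different categories across studies, keep the most favorable.
CATEGORY_FAVORABILITY = ("likely", "ubiquitous", "unlikely", "questionable", "unknown")

DEFAULT_PROMISCUITY_THRESHOLD = 9

_CALL_COLUMNS = {"accession", "study_id", "disease", "category", "direction"}


def _canon_disease(series: pd.Series, synonyms: Mapping[str, str] | None) -> pd.Series:
    if not synonyms:
        return series.astype(str)
    return series.astype(str).map(lambda d: synonyms.get(d, d))


def _best_category(cats: Iterable[str]) -> str:
    return min(cats, key=CATEGORY_FAVORABILITY.index)


@dataclass
class AuditSummary:
    """Aggregate audit of a classified report table."""

    n_reports: int
    unique_mirnas: int
    per_mirna: pd.DataFrame          # accession → n_studies, n_diseases
    merged: pd.DataFrame             # one row per (accession, disease) pair
    report_tallies: pd.DataFrame     # category → count, percent
    merged_tallies: pd.DataFrame
    promiscuous: frozenset[str]
    promiscuity_threshold: int
    n_multi_manuscript: int = 0
    replication: pd.DataFrame | None = None
    replication_pooled: dict = field(default_factory=dict)

    def write_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_mirna.to_csv(directory / "per_mirna.tsv", sep="\t")
        self.merged.to_csv(directory / "merged_pairs.tsv", sep="\t", index=False)
        self.report_tallies.to_csv(directory / "report_tallies.tsv", sep="\t")
        self.merged_tallies.to_csv(directory / "merged_tallies.tsv", sep="\t")
        with open(directory / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(self.describe())

    def describe(self) -> str:
        lines = [
            f"reports: {self.n_reports}",
            f"unique microRNAs: {self.unique_mirnas}",
            f"in >1 manuscript: {self.n_multi_manuscript}",
            f"merged (microRNA, disease) pairs: {len(self.merged)}",
            f"promiscuous (>= {self.promiscuity_threshold} diseases): "
            + (", ".join(sorted(self.promiscuous)) or "none"),
        ]
        if self.replication_pooled:
            r = self.replication_pooled
            lines.append(
                f"replication: {r['n_replicated']} of {r['n_biomarkers']} "
                f"replicated, {r['n_opposite']} opposite-direction"
            )
        return "\n".join(lines) + "\n"


def dedupe_and_count(
    calls: pd.DataFrame,
    *,
    disease_synonyms: Mapping[str, str] | None = None,
    promiscuity_threshold: int = DEFAULT_PROMISCUITY_THRESHOLD,
    with_replication: bool = True,
) -> AuditSummary:
    """Collapse a classified report table to unique microRNAs and pairs.

    ``calls`` needs columns accession, study_id, disease, category,
    direction (the output of ``classify_table`` or ``read_study_grid``).
    Rows without an accession (unresolved names) are keyed by their printed
    name so they still tally.  Similar disease processes merge through the
    optional ``disease_synonyms`` map (printed label → canonical label).
    """
    lacking = _CALL_COLUMNS - set(calls.columns)
    if lacking:
        raise ValueError(f"calls table lacks columns {sorted(lacking)}")
    df = calls.copy()
    df["accession"] = df["accession"].where(
        df["accession"].notna() & (df["accession"] != ""),
        "name:" + df.get("mirna_name", df["accession"]).astype(str),
    )
    df["disease"] = _canon_disease(df["disease"], disease_synonyms)

    per_mirna = df.groupby("accession").agg(
        n_studies=("study_id", "nunique"),
        n_diseases=("disease", "nunique"),
        n_reports=("study_id", "size"),
    )
    merged = (
        df.groupby(["accession", "disease"])
        .agg(
            category=("category", _best_category),
            n_studies=("study_id", "nunique"),
            n_reports=("study_id", "size"),
        )
        .reset_index()
    )
    promiscuous = frozenset(
        per_mirna.index[per_mirna["n_diseases"] >= promiscuity_threshold]
    )
    summary = AuditSummary(
        n_reports=len(df),
        unique_mirnas=len(per_mirna),
        per_mirna=per_mirna,
        merged=merged,
        report_tallies=tally_categories(df["category"]),
        merged_tallies=tally_categories(merged["category"]),
        promiscuous=promiscuous,
        promiscuity_threshold=promiscuity_threshold,
        n_multi_manuscript=int((per_mirna["n_studies"] > 1).sum()),
    )
    if with_replication:
        summary.replication, summary.replication_pooled = replication_stats(
            df, disease_synonyms=None  # already canonicalized above
        )
    logger.info("audit: %s", summary.describe().replace("\n", "; "))
    return summary


def replication_stats(
    calls: pd.DataFrame,
    *,
    disease_synonyms: Mapping[str, str] | None = None,
    min_studies: int = 2,
    by_compartment: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Within-disease replication and direction-conflict counts.

    Only diseases studied by at least ``min_studies`` distinct studies are
    scored (others are skipped with a log line).  Within such a disease, a
    microRNA is *replicated* when reported by two or more studies with
    concordant direction, and *opposite* when its directions disagree; a
    "mixed" direction in any single report makes the microRNA
    discordant-eligible (counted as opposite when multiply reported).
    ``by_compartment`` stratifies the analysis within (disease,
    compartment) strata instead of pooling compartments.
    """
    df = calls.copy()
    df["disease"] = _canon_disease(df["disease"], disease_synonyms)
    group_cols = ["disease", "compartment"] if by_compartment else ["disease"]
    records = []
    for keys, sub in df.groupby(group_cols):
        n_studies = sub["study_id"].nunique()
        if n_studies < min_studies:
            logger.info(
                "replication_stats: %s has %d study(ies); skipped", keys, n_studies
            )
            continue
        n_rep = n_opp = 0
        for _, mi in sub.groupby("accession"):
            if mi["study_id"].nunique() < 2:
                continue
            directions = set(mi["direction"])
            if "mixed" in directions or len(directions) > 1:
                n_opp += 1
            else:
                n_rep += 1
        rec = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        rec.update(
            n_studies=n_studies,
            n_biomarkers=sub["accession"].nunique(),
            n_replicated_same_direction=n_rep,
            n_opposite_direction=n_opp,
        )
        records.append(rec)
    table = pd.DataFrame(
        records,
        columns=group_cols
        + [
            "n_studies",
            "n_biomarkers",
            "n_replicated_same_direction",
            "n_opposite_direction",
        ],
    )
    pooled = {
        "n_diseases": len(table),
        "n_biomarkers": int(table["n_biomarkers"].sum()) if len(table) else 0,
        "n_replicated": int(table["n_replicated_same_direction"].sum())
        if len(table)
        else 0,
        "n_opposite": int(table["n_opposite_direction"].sum()) if len(table) else 0,
    }
    return table, pooled


def tally_categories(categories: Sequence[str] | pd.Series) -> pd.DataFrame:
    """Counts and integer-rounded percentages per plausibility category.

    Indexed by the five categories in canonical order; the denominator is
    recorded in the DataFrame attrs.  Integer rounding follows the display
    convention of published tallies, so percentages sum to 100 ± 1.
    """
    cats = pd.Series(list(categories), dtype=object)
    counts = cats.value_counts()
    out = pd.DataFrame(
        {
            "count": [int(counts.get(c, 0)) for c in CATEGORIES],
            "percent": [
                int(round(100.0 * counts.get(c, 0) / len(cats))) if len(cats) else 0
                for c in CATEGORIES
            ],
        },
        index=pd.Index(CATEGORIES, name="category"),
    )
    out.attrs["denominator"] = int(len(cats))
    return out


_POOR_NONE_TOKENS = (
    "none", "no normalization", "not reported", "unreported", "unknown", "n/a",
)


def normalization_quality(report: BiomarkerReport) -> str:
    """Class a study's qRT-PCR normalization strategy as poor or acceptable.

    Poor: RNU6B (U6) evaluated in cell-free compartments (serum, plasma,
    blood NOS) where it is unstable; no or unreported normalization; or
    miR-451a (a red-cell microRNA confounded by hemolysis) as normalizer.
    Acceptable: anything else — spike-ins, RNU6B in PBMC, human microRNAs
    other than miR-451a.  Non-text input is flagged "unclassified" (exclude
    such rows from χ² denominators).
    """
    text = report.normalization_method
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return "unclassified"
    t = str(text).strip().casefold()
    if not t or any(tok in t for tok in _POOR_NONE_TOKENS):
        return "poor"
    if ("rnu6" in t or "u6" in t) and report.compartment in (
        "serum", "plasma", "blood_NOS",
    ):
        return "poor"
    if "451" in t:
        return "poor"
    return "acceptable"


def chi_square_2x2(table: Sequence[Sequence[float]] | np.ndarray) -> tuple[float, float]:
    """Pearson χ² on a 2×2 table, df = 1, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2×2 table")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch unequal-variance t-test (Satterthwaite df), two-sided."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) <= 0 or np.var(y, ddof=1) <= 0:
        raise ValueError("each sample needs positive variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# --- study-grid (studies × microRNAs) text layout ---------------------------

_CODE_TO_CATEGORY = {
    "L": "likely", "Q": "questionable", "U": "ubiquitous",
    "N": "unlikely", "K": "unknown",
}
_CATEGORY_TO_CODE = {v: k for k, v in _CODE_TO_CATEGORY.items()}
_SIGN_TO_DIRECTION = {"+": "up", "-": "down", "~": "mixed"}
_DIRECTION_TO_SIGN = {v: k for k, v in _SIGN_TO_DIRECTION.items()}

GRID_META_COLUMNS = ("study_id", "disease", "compartment")


def read_study_grid(
    path: str | Path, key: NomenclatureKey | None = None
) -> pd.DataFrame:
    """Read a studies × microRNAs grid into a long classified-calls table.

    Layout (TSV): columns ``study_id``, ``disease``, ``compartment``, then
    one column per microRNA name.  A non-empty cell means the study
    reported that microRNA, coded as a category letter plus a direction
    sign — ``L``/``Q``/``U``/``N``/``K`` for likely / questionable /
    ubiquitous / unlikely / unknown and ``+``/``-``/``~`` for up / down /
    mixed (e.g. ``L+``); the sign may be omitted (direction "mixed").
    Names are harmonized to accessions through ``key`` when given;
    unresolvable or un-keyed names keep the printed name as accession.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lacking = [c for c in GRID_META_COLUMNS if c not in df.columns]
    if lacking:
        raise ValueError(f"study grid lacks columns {lacking}")
    mirna_cols = [c for c in df.columns if c not in GRID_META_COLUMNS]
    acc_of: dict[str, str] = {}
    for name in mirna_cols:
        if key is None:
            acc_of[name] = name
        else:
            try:
                acc_of[name] = harmonize(name, key).accession
            except UnknownMirnaError:
                acc_of[name] = name
    rows = []
    for _, r in df.iterrows():
        for name in mirna_cols:
            cell = r[name]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if not cell:
                continue
            code, sign = cell[0].upper(), cell[1:].strip()
            if code not in _CODE_TO_CATEGORY:
                raise ValueError(
                    f"unrecognized category code {cell!r} for study "
                    f"{r['study_id']}, microRNA {name}"
                )
            rows.append(
                {
                    "study_id": str(r["study_id"]),
                    "disease": str(r["disease"]),
                    "compartment": str(r["compartment"]),
                    "mirna_name": name,
                    "accession": acc_of[name],
                    "direction": _SIGN_TO_DIRECTION.get(sign, "mixed"),
                    "category": _CODE_TO_CATEGORY[code],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "study_id", "disease", "compartment", "mirna_name", "accession",
            "direction", "category",
        ],
    )


def write_study_grid(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a long classified-calls table in the grid layout of
    :func:`read_study_grid` (inverse operation; one row per study)."""
    studies = calls[list(GRID_META_COLUMNS)].drop_duplicates("study_id")
    names = list(dict.fromkeys(calls["mirna_name"]))
    grid = pd.DataFrame("", index=studies["study_id"], columns=names)
    for _, r in calls.iterrows():
        code = _CATEGORY_TO_CODE[r["category"]]
        sign = _DIRECTION_TO_SIGN.get(r["direction"], "~")
        grid.loc[r["study_id"], r["mirna_name"]] = code + sign
    out = studies.set_index("study_id").join(grid)
    out.to_csv(path, sep="\t")
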