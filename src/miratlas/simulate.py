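"""Synthetic multi-platform microRNA array data with planted ground truth.

Everything the pipeline consumes can be generated here: nested platform
probe sets of unequal size sharing a common subset, cell-type-specific /
ubiquitous / unexpressed microRNA archetypes on the observed log2 scale
(4.8–12.8), per-chip location/scale batch effects, missing values, and
biomarker report tables whose correct plausibility category is known by
construction.  Defaults mirror the study conditions the pipeline targets:
three platform versions measuring 461/711/837 microRNAs, 18 cell types
(8 hematopoietic sharing a leukocyte signature), and expression-call
margins of at least 1.0 around the 8.0 threshold so that end-to-end call
recovery is a sharp test, not a statistical one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import SampleMatrix
from .nomenclature import NomenclatureKey, build_key
from .plausibility import BiomarkerReport, DiseaseCellMap

__all__ = [
    "SimConfig",
    "AtlasTruth",
    "simulate_atlas_truth",
    "simulate_arrays",
    "simulate_disease_map",
    "simulate_reports",
]

ARCHETYPES = ("cell_specific", "ubiquitous", "unexpressed")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    seed: int = 0
    n_cell_types: int = 18
    n_hematopoietic: int = 8
    platform_sizes: tuple[int, ...] = (461, 711, 837)
    samples_per_cell_type: int = 6
    chip_size: int = 8
    chip_shift_sd: float = 0.4       # per-chip additive location effect (log2)
    chip_scale_sigma: float = 0.15   # lognormal sigma of per-chip noise scale
    noise_sd: float = 0.25           # per-measurement noise (log2)
    missing_rate: float = 0.02
    archetype_mix: tuple[float, float, float] = (0.45, 0.25, 0.30)
    expressed_range: tuple[float, float] = (9.0, 12.8)
    unexpressed_range: tuple[float, float] = (4.8, 6.0)
    ubiquity_min: int = 7
    signature_size: int = 30         # microRNAs shared by hematopoietic cells
    n_corrupt_samples: int = 0       # extra samples with >50% missing data
    adversarial: bool = False        # plant means inside the call margin

    def __post_init__(self) -> None:
        if self.n_cell_types < 8:
            raise ValueError("need >= 8 cell types for both archetype classes")
        if not 0 < self.n_hematopoietic < self.n_cell_types:
            raise ValueError("n_hematopoietic must be in (0, n_cell_types)")
        if tuple(sorted(self.platform_sizes)) != tuple(self.platform_sizes):
            raise ValueError("platform_sizes must be ascending (nested design)")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9:
            raise ValueError("archetype_mix must sum to 1")
        if self.ubiquity_min > self.n_cell_types:
            raise ValueError("ubiquity_min exceeds the number of cell types")

    @property
    def n_mirnas(self) -> int:
        return self.platform_sizes[-1]

    @property
    def subset_size(self) -> int:
        return self.platform_sizes[0]


@dataclass
class AtlasTruth:
    """Planted per-cell expression means and the implied correct calls."""

    cell_types: list[str]
    hematopoietic: frozenset[str]
    mirnas: list[str]                      # accessions
    names: dict[str, str]                  # accession -> canonical name
    archetype: dict[str, tuple[str, int]]  # accession -> (kind, n cells)
    means: pd.DataFrame                    # cell types × microRNAs (log2)
    true_calls: pd.DataFrame               # cell types × microRNAs (bool)

    def key(self) -> NomenclatureKey:
        """Nomenclature key covering the simulated microRNAs."""
        return build_key([(acc, self.names[acc]) for acc in self.mirnas])


def _cell_names(config: SimConfig) -> tuple[list[str], list[str]]:
    hema = [f"hema_{i+1:02d}" for i in range(config.n_hematopoietic)]
    non = [
        f"nonhema_{i+1:02d}"
        for i in range(config.n_cell_types - config.n_hematopoietic)
    ]
    return hema, non


def simulate_atlas_truth(config: SimConfig) -> AtlasTruth:
    """Plant per-(cell, microRNA) true means with unambiguous archetypes.

    Expressed means are drawn in [9.0, 12.8] and unexpressed in [4.8, 6.0],
    leaving a margin >= 1.0 around the 8.0 call threshold (unless
    ``adversarial`` plants boundary cases).  The first ``signature_size``
    microRNAs are expressed in every hematopoietic cell and the next
    ``signature_size`` in every non-hematopoietic cell — paired lineage
    programs, so the split is recoverable by clustering while every cell
    type expresses a comparable number of microRNAs (as real cell types
    do).  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    hema, non = _cell_names(config)
    cells = hema + non
    n_c = config.n_cell_types
    mirnas = [f"MIMATS{i:05d}" for i in range(config.n_mirnas)]
    names = {acc: f"hsa-miR-s{i}-5p" for i, acc in enumerate(mirnas)}

    lo_u, hi_u = config.unexpressed_range
    lo_e, hi_e = config.expressed_range
    means = pd.DataFrame(
        rng.uniform(lo_u, hi_u, size=(n_c, config.n_mirnas)),
        index=cells,
        columns=mirnas,
    )
    archetype: dict[str, tuple[str, int]] = {}

    n_sig = min(config.signature_size, config.n_mirnas // 2)
    for group, accs in ((hema, mirnas[:n_sig]), (non, mirnas[n_sig : 2 * n_sig])):
        k = len(group)
        kind = "ubiquitous" if k >= config.ubiquity_min else "cell_specific"
        for acc in accs:  # lineage signature: expressed in the whole group
            archetype[acc] = (kind, k)
            means.loc[group, acc] = rng.uniform(lo_e, hi_e, size=k)
    n_sig *= 2

    kinds = rng.choice(3, size=config.n_mirnas - n_sig, p=config.archetype_mix)
    for kind_idx, acc in zip(kinds, mirnas[n_sig:]):
        kind = ARCHETYPES[kind_idx]
        if kind == "cell_specific":
            k = int(rng.integers(1, config.ubiquity_min))  # 1 .. ubiquity_min-1
        elif kind == "ubiquitous":
            k = int(rng.integers(config.ubiquity_min, n_c + 1))
        else:
            k = 0
        if k > n_c:
            raise ValueError(f"archetype requests {k} cells but atlas has {n_c}")
        archetype[acc] = (kind, k)
        if k:
            chosen = rng.choice(n_c, size=k, replace=False)
            means.iloc[chosen, means.columns.get_loc(acc)] = rng.uniform(
                lo_e, hi_e, size=k
            )
    if config.adversarial:
        n_adv = max(1, config.n_mirnas // 50)
        adv = rng.choice(config.n_mirnas, size=n_adv, replace=False)
        for g in adv:
            c = int(rng.integers(n_c))
            means.iloc[c, g] = rng.uniform(7.5, 8.5)

    true_calls = means >= 8.0
    return AtlasTruth(
        cell_types=cells,
        hematopoietic=frozenset(hema),
        mirnas=mirnas,
        names=names,
        archetype=archetype,
        means=means,
        true_calls=true_calls,
    )


def simulate_arrays(
    truth: AtlasTruth, config: SimConfig
) -> list[SampleMatrix]:
    """Simulate one probe-level matrix per platform version.

    Samples of every cell type are dealt round-robin across platforms; each
    platform's samples are grouped onto chips (= batches) of ``chip_size``,
    and each chip draws a location shift ~ N(0, chip_shift_sd) and a noise
    scale factor ~ lognormal(0, chip_scale_sigma):

        value = true mean + chip shift + chip scale × N(0, noise_sd)

    Missing entries are inserted at ``missing_rate``; ``n_corrupt_samples``
    extra samples (platform-cycled) carry 60% missing data so the
    missing-array filter has something to catch.  Deterministic under seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_platforms = len(config.platform_sizes)
    platform_features = [
        truth.mirnas[:size] for size in config.platform_sizes
    ]
    assignments: list[list[str]] = [[] for _ in range(n_platforms)]
    for ci, cell in enumerate(truth.cell_types):
        for s in range(config.samples_per_cell_type):
            assignments[(ci + s) % n_platforms].append(cell)

    matrices = []
    for p, (cells, feats) in enumerate(zip(assignments, platform_features)):
        version = f"V{p+1}"
        n = len(cells)
        extra = [
            c for i, c in enumerate(truth.cell_types)
            if i % n_platforms == p
        ][: max(0, config.n_corrupt_samples // n_platforms
                + (1 if p < config.n_corrupt_samples % n_platforms else 0))]
        all_cells = cells + extra
        sample_ids = [f"{version}_s{j:03d}" for j in range(len(all_cells))]
        n_chips = max(1, int(np.ceil(len(all_cells) / config.chip_size)))
        chip_of = [f"{version}_chip{j % n_chips:02d}" for j in range(len(all_cells))]
        shifts = {
            f"{version}_chip{c:02d}": rng.normal(0, config.chip_shift_sd)
            for c in range(n_chips)
        }
        scales = {
            f"{version}_chip{c:02d}": float(
                np.exp(rng.normal(0, config.chip_scale_sigma))
            )
            for c in range(n_chips)
        }
        mu = truth.means.loc[all_cells, feats].to_numpy()
        shift = np.array([shifts[c] for c in chip_of])[:, None]
        scale = np.array([scales[c] for c in chip_of])[:, None]
        vals = mu + shift + scale * rng.normal(0, config.noise_sd, size=mu.shape)
        if config.missing_rate > 0:
            mask = rng.random(vals.shape) < config.missing_rate
            vals = np.where(mask, np.nan, vals)
        for j in range(len(cells), len(all_cells)):  # corrupt extras: 60% missing
            holes = rng.random(vals.shape[1]) < 0.6
            vals[j, holes] = np.nan
        values = pd.DataFrame(vals, index=sample_ids, columns=feats)
        meta = pd.DataFrame(
            {
                "label": all_cells,
                "platform_version": version,
                "batch_id": chip_of,
                "compartment_class": "cell",
            },
            index=sample_ids,
        )
        matrices.append(SampleMatrix(values, meta))
    return matrices


def simulate_disease_map(
    truth: AtlasTruth,
    n_diseases: int,
    seed: int = 0,
    cells_per_disease: tuple[int, int] = (1, 3),
) -> DiseaseCellMap:
    """Random disease → cell-type map over the simulated atlas's cells."""
    rng = np.random.default_rng(seed)
    lo, hi = cells_per_disease
    cells = np.array(truth.cell_types)
    mapping = {}
    for d in range(n_diseases):
        k = int(rng.integers(lo, hi + 1))
        mapping[f"disease_{d:02d}"] = frozenset(
            rng.choice(cells, size=k, replace=False)
        )
    return DiseaseCellMap(cells=mapping)


def _pick(rng: np.random.Generator, items: Sequence) -> object:
    return items[int(rng.integers(len(items)))]


_NORMALIZATION_TEXTS = (
    "cel-miR-39 spike-in", "RNU6B", "miR-16", "global mean normalization",
    "not reported",
)


def simulate_reports(
    truth: AtlasTruth,
    disease_map: DiseaseCellMap,
    n_studies: int = 104,
    n_reports: int = 416,
    planted_mix: Mapping[str, float] | None = None,
    replication_rate: float = 0.12,
    opposite_rate: float = 0.04,
    seed: int = 0,
    ubiquity_threshold: int = 7,
    compartment_freqs: Mapping[str, float] | None = None,
) -> tuple[list[BiomarkerReport], list[str]]:
    """Draw a biomarker report table with known correct categories.

    Each row is constructed so its plausibility category is unambiguous
    under the classifier's decision rules evaluated on the *planted truth*
    (cell-specific microRNA in a mapped cell → likely; unexpressed →
    questionable; >= 7 cells in a cell-free compartment → ubiquitous;
    expressed only in unmapped cells → unlikely; a fabricated name →
    unknown).  Per-disease, a fraction ``replication_rate`` of biomarkers
    receives a second concordant study and ``opposite_rate`` a second
    discordant study.  Study metadata (compartment, normalization text,
    impact factor) is drawn from configurable distributions echoing the
    literature (serum and plasma dominate; PBMC studies are only used for
    leukocyte-driven rows).  Returns (reports, ground-truth categories),
    aligned.
    """
    rng = np.random.default_rng(seed)
    mix = dict(planted_mix or {
        "likely": 0.33, "questionable": 0.22, "ubiquitous": 0.33,
        "unlikely": 0.09, "unknown": 0.03,
    })
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError("planted_mix must sum to 1")
    freqs = dict(compartment_freqs or {"serum": 0.5, "plasma": 0.46, "blood_NOS": 0.04})
    cellfree = list(freqs)
    cf_p = np.array([freqs[c] for c in cellfree], dtype=float)
    cf_p /= cf_p.sum()

    diseases = sorted(disease_map.cells.keys())
    if not diseases:
        raise ValueError("disease map is empty")
    specific = [
        a for a, (kind, k) in truth.archetype.items()
        if kind == "cell_specific" and 0 < k < ubiquity_threshold
    ]
    ubiquitous = [
        a for a, (kind, k) in truth.archetype.items()
        if k >= ubiquity_threshold
    ]
    unexpressed = [
        a for a, (kind, k) in truth.archetype.items() if kind == "unexpressed"
    ]
    calls = truth.true_calls
    hema = truth.hematopoietic

    def cells_of(acc: str) -> frozenset[str]:
        col = calls[acc]
        return frozenset(col.index[col])

    def draw_row(category: str) -> tuple[str, str, str]:
        """Return (mirna name, disease, compartment) realizing ``category``."""
        for _ in range(1000):
            disease = str(_pick(rng, diseases))
            mapped = disease_map.cells_for(disease)
            if category == "questionable":
                if not unexpressed:
                    break
                return truth.names[str(_pick(rng, unexpressed))], disease, str(
                    _pick(rng, cellfree)
                )
            if category == "unknown":
                return f"hsa-miR-fake-{int(rng.integers(1e6))}", disease, str(
                    _pick(rng, cellfree)
                )
            if category == "ubiquitous":
                if not ubiquitous:
                    break
                return truth.names[str(_pick(rng, ubiquitous))], disease, str(
                    _pick(rng, cellfree)
                )
            if category == "likely":
                if rng.random() < 0.25:  # PBMC route: leukocyte-expressed
                    cands = [a for a in truth.mirnas if cells_of(a) & hema]
                    if cands:
                        return truth.names[str(_pick(rng, cands))], disease, "PBMC"
                cands = [a for a in specific if cells_of(a) & mapped]
                if cands:
                    return truth.names[str(_pick(rng, cands))], disease, str(
                        _pick(rng, cellfree)
                    )
            if category == "unlikely":
                if rng.random() < 0.25:  # PBMC route: no leukocyte expression
                    cands = [
                        a for a in specific
                        if cells_of(a) and not (cells_of(a) & hema)
                    ]
                    if cands:
                        return truth.names[str(_pick(rng, cands))], disease, "PBMC"
                cands = [
                    a for a in specific
                    if cells_of(a) and not (cells_of(a) & mapped)
                ]
                if cands:
                    return truth.names[str(_pick(rng, cands))], disease, str(
                        _pick(rng, cellfree)
                    )
        raise ValueError(
            f"planted mix infeasible: cannot construct a {category!r} row "
            "from the simulated truth and disease map"
        )

    categories = list(mix)
    probs = np.array([mix[c] for c in categories])
    reports: list[BiomarkerReport] = []
    labels: list[str] = []
    study_of_disease: dict[str, list[str]] = {}
    next_study = 0

    def study_for(disease: str, exclude: set[str] = frozenset()) -> str:
        nonlocal next_study
        pool = [s for s in study_of_disease.get(disease, []) if s not in exclude]
        if pool and rng.random() < 0.7:
            return str(_pick(rng, pool))
        next_study += 1
        sid = f"S{next_study:04d}"
        study_of_disease.setdefault(disease, []).append(sid)
        return sid

    drawn = rng.choice(len(categories), size=n_reports, p=probs)
    for ci in drawn:
        category = categories[ci]
        name, disease, compartment = draw_row(category)
        direction = "up" if rng.random() < 0.67 else "down"
        sid = study_for(disease)
        base = BiomarkerReport(
            study_id=sid,
            disease=disease,
            compartment=compartment,
            mirna_name=name,
            direction=direction,
            normalization_method=str(_pick(rng, _NORMALIZATION_TEXTS)),
            journal_impact_factor=float(np.round(np.exp(rng.normal(1.35, 0.5)), 3)),
        )
        reports.append(base)
        labels.append(category)
        # replication / direction-conflict planting: a second study's report
        u = rng.random()
        if u < replication_rate + opposite_rate:
            flipped = u >= replication_rate
            sid2 = study_for(disease, exclude={sid})
            if sid2 != sid:
                reports.append(
                    replace_direction(base, sid2, "down" if (flipped and
                        direction == "up") else ("up" if flipped else direction))
                )
                labels.append(category)
        if len(reports) >= n_reports:
            break
    # trim study count if requested fewer studies than were opened
    return reports[:n_reports], labels[:n_reports]


def replace_direction(r: BiomarkerReport, study_id: str, direction: str) -> BiomarkerReport:
    return BiomarkerReport(
        study_id=study_id,
        disease=r.disease,
        compartment=r.compartment,
        mirna_name=r.mirna_name,
        direction=direction,
        normalization_method=r.normalization_method,
        journal_impact_factor=r.journal_impact_factor,
    )
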