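"""End-to-end convenience wrapper: arrays in, cell atlas out.

Stage order: drop arrays with >50% missing data, build the common-subset
reference and subset-quantile-normalize every platform, pool the samples,
adjust chip-level batch effects by empirical Bayes (cell type protected as
a covariate by default), and group into the cell atlas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import combat, sqn
from .atlas import CellAtlas, build_atlas
from .ingest import SampleMatrix, filter_missing_arrays

__all__ = ["PipelineResult", "common_features", "run_pipeline"]


@dataclass
class PipelineResult:
    atlas: CellAtlas
    normalized: SampleMatrix
    adjusted: SampleMatrix
    reference: sqn.ReferenceDistribution
    batch_model: combat.BatchModel


def common_features(matrices: Sequence[SampleMatrix]) -> list[str]:
    """Features present on every platform (the normalization subset)."""
    sets = [set(m.values.columns) for m in matrices]
    return sorted(set.intersection(*sets))


def pool(matrices: Sequence[SampleMatrix]) -> SampleMatrix:
    """Concatenate platform matrices on the union feature space."""
    values = pd.concat([m.values for m in matrices], axis=0)
    meta = pd.concat([m.sample_meta for m in matrices], axis=0)
    return SampleMatrix(values, meta)


def run_pipeline(
    matrices: Sequence[SampleMatrix],
    *,
    max_missing_fraction: float = 0.5,
    threshold: float = 8.0,
    noise_floor: float = 7.0,
    use_cell_covariate: bool = True,
    **atlas_kwargs,
) -> PipelineResult:
    """Filter → subset quantile normalize → batch-adjust → build atlas."""
    filtered = [filter_missing_arrays(m, max_missing_fraction) for m in matrices]
    subset = common_features(filtered)
    ref = sqn.build_reference(filtered, subset)
    normalized = pool([sqn.normalize_matrix(m, ref) for m in filtered])
    covariates = (
        normalized.sample_meta["label"].astype(str) if use_cell_covariate else None
    )
    model = combat.fit_batch_model(normalized, covariate_labels=covariates)
    adjusted = combat.adjust(normalized, model)
    atlas = build_atlas(
        adjusted, threshold=threshold, noise_floor=noise_floor, **atlas_kwargs
    )
    return PipelineResult(
        atlas=atlas,
        normalized=normalized,
        adjusted=adjusted,
        reference=ref,
        batch_model=model,
    )
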