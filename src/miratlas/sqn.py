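"""Modified subset quantile normalization across array platform versions.

Full quantile normalization forces every sample onto one value distribution,
which is wrong when platforms target different microRNA sets.  Subset
quantile normalization relaxes this: distributional equality is enforced
only on a subset of features, and every other feature is mapped through its
relationship to that subset.  Here the subset is the features **common to
all platform versions** — it is large (hundreds of microRNAs), so a
nonparametric rank-interpolation construction is stable and is used instead
of the control-probe mixture-model formulation devised for small negative-
control subsets.

Mechanics, per sample with n_s non-missing subset values:

* a reference distribution is the across-sample mean of the sorted subset
  values interpolated onto the plotting-position grid p_k = (k − 0.5)/m;
* a subset feature at (average, for ties) rank r receives the reference
  evaluated at p = (r − 0.5)/n_s;
* a non-subset feature with value v receives the reference evaluated at
  F̂(v), the piecewise-linear empirical CDF of the sample's subset values,
  clamped to [0.5/n_s, 1 − 0.5/n_s] (flat outside the observed range — no
  extrapolated extremes);
* missing values stay missing.  Within-sample ordering is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ingest import SampleMatrix

__all__ = [
    "ReferenceDistribution",
    "build_reference",
    "sqn_normalize",
    "normalize_matrix",
]

logger = logging.getLogger(__name__)

#: A sample must share at least this many non-missing subset features
#: with the reference for rank interpolation to be meaningful.
MIN_SUBSET_VALUES = 3


def _plotting_grid(m: int) -> np.ndarray:
    return (np.arange(1, m + 1) - 0.5) / m


@dataclass
class ReferenceDistribution:
    """Mean subset distribution on a plotting-position grid."""

    quantile_grid: np.ndarray
    reference_values: np.ndarray
    subset_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.quantile_grid = np.asarray(self.quantile_grid, dtype=float)
        self.reference_values = np.asarray(self.reference_values, dtype=float)
        if self.quantile_grid.shape != self.reference_values.shape:
            raise ValueError("grid and values must have equal length")
        if not (np.diff(self.quantile_grid) > 0).all():
            raise ValueError("quantile grid must be strictly increasing")
        if (self.quantile_grid <= 0).any() or (self.quantile_grid >= 1).any():
            raise ValueError("quantile grid must lie in (0, 1)")
        if (np.diff(self.reference_values) < 0).any():
            raise ValueError("reference values must be non-decreasing")
        self.subset_ids = tuple(self.subset_ids)

    def evaluate(self, p: np.ndarray | float) -> np.ndarray | float:
        """Reference quantile function at probabilities ``p`` (flat-clamped)."""
        return np.interp(p, self.quantile_grid, self.reference_values)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# subset_size={len(self.subset_ids)}\n")
            fh.write("# subset_ids=" + ";".join(self.subset_ids) + "\n")
            fh.write("probability\tvalue\n")
            for p, v in zip(self.quantile_grid, self.reference_values):
                fh.write(f"{p:.10g}\t{v:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceDistribution":
        subset_ids: tuple[str, ...] = ()
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("# subset_ids="):
                field = line.split("=", 1)[1].strip()
                subset_ids = tuple(s for s in field.split(";") if s)
            elif not line.startswith("#"):
                body.append(line)
        df = pd.read_csv(pd.io.common.StringIO("".join(body)), sep="\t")
        return cls(df["probability"].to_numpy(), df["value"].to_numpy(), subset_ids)


def build_reference(
    matrices: Sequence[SampleMatrix], subset_ids: Iterable[str]
) -> ReferenceDistribution:
    """Pool all samples' sorted subset values into a mean reference.

    Each sample's non-missing subset values are sorted, placed on the
    plotting positions (r − 0.5)/n_s, and linearly interpolated onto the
    common grid p_k = (k − 0.5)/m with m = |subset_ids|; the reference is
    the across-sample mean at each grid point.  Samples with fewer than
    three non-missing subset values are excluded with a warning.  A subset
    feature absent from any matrix is an error (the subset is by definition
    common to all platforms).
    """
    subset = sorted(set(subset_ids))
    if not subset:
        raise ValueError("subset_ids is empty")
    for mat in matrices:
        absent = [s for s in subset if s not in mat.values.columns]
        if absent:
            raise ValueError(
                f"subset features absent from a platform matrix: {absent[:5]}"
            )
    m = len(subset)
    grid = _plotting_grid(m)
    curves = []
    for mat in matrices:
        sub = mat.values[subset]
        for sample_id, row in sub.iterrows():
            vals = np.sort(row.to_numpy(dtype=float))
            vals = vals[~np.isnan(vals)]
            n_s = vals.size
            if n_s < MIN_SUBSET_VALUES:
                logger.warning(
                    "build_reference: sample %s has only %d non-missing subset "
                    "values; excluded from the reference", sample_id, n_s,
                )
                continue
            curves.append(np.interp(grid, _plotting_grid(n_s), vals))
    if not curves:
        raise ValueError("no sample contributed to the reference")
    return ReferenceDistribution(grid, np.mean(curves, axis=0), tuple(subset))


def _subset_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Knots of the piecewise-linear empirical CDF with average-rank ties.

    Returns (unique sorted values, their plotting positions).  At a value
    tied across ranks r..r+k the position is (mean rank − 0.5)/n_s, so the
    CDF agrees with average-rank plotting positions on the sample itself.
    """
    n_s = values.size
    ranks = rankdata(values, method="average")
    order = np.argsort(values, kind="stable")
    xs, ps = [], []
    for idx in order:
        if xs and values[idx] == xs[-1]:
            continue
        xs.append(values[idx])
        ps.append((ranks[idx] - 0.5) / n_s)
    return np.asarray(xs), np.asarray(ps)


def sqn_normalize(
    sample: pd.Series,
    subset_ids: Iterable[str],
    ref: ReferenceDistribution,
) -> pd.Series:
    """Normalize one sample's feature vector against the reference.

    Subset features are mapped by rank (ties averaged); non-subset features
    are mapped through the sample's subset CDF.  Both paths go through one
    monotone map value -> probability -> reference, so within-sample order
    is preserved and subset/non-subset features with equal values agree.
    """
    subset = set(subset_ids)
    is_subset = sample.index.isin(subset)
    sub_vals = sample[is_subset].to_numpy(dtype=float)
    sub_vals = sub_vals[~np.isnan(sub_vals)]
    n_s = sub_vals.size
    if n_s < MIN_SUBSET_VALUES:
        raise ValueError(
            f"sample {sample.name!r} shares only {n_s} non-missing subset "
            f"features with the reference (need >= {MIN_SUBSET_VALUES})"
        )
    xs, ps = _subset_cdf(sub_vals)
    lo, hi = 0.5 / n_s, 1.0 - 0.5 / n_s

    vals = sample.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    ok = ~np.isnan(vals)
    probs = np.interp(vals[ok], xs, ps)  # flat-clamped to [ps[0], ps[-1]]
    probs = np.clip(probs, lo, hi)
    out[ok] = ref.evaluate(probs)
    return pd.Series(out, index=sample.index, name=sample.name)


def normalize_matrix(
    m: SampleMatrix, ref: ReferenceDistribution
) -> SampleMatrix:
    """Apply :func:`sqn_normalize` to every sample of a matrix."""
    rows = [sqn_normalize(row, ref.subset_ids, ref) for _, row in m.values.iterrows()]
    return SampleMatrix(pd.DataFrame(rows, index=m.values.index), m.sample_meta.copy())
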