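"""Cell-type × microRNA expression atlas: calls, queries, clustering.

After normalization and batch adjustment, per-sample values are grouped by
cell type.  A microRNA is *called expressed* in a cell type when any one
sample of that cell type reaches the expression threshold (default 8.0 on
the log2 scale, inclusive; values below the 7.0 noise floor are array
noise).  The per-cell mean profile is kept for clustering and display but
never drives calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .ingest import SampleMatrix
from .nomenclature import MirnaId

__all__ = [
    "CellAtlas",
    "ExpressedCells",
    "ClusterResult",
    "build_atlas",
    "expressed_cells",
    "cluster_cells",
    "read_atlas_values",
]

DEFAULT_THRESHOLD = 8.0
DEFAULT_NOISE_FLOOR = 7.0


@dataclass
class CellAtlas:
    """Per-cell-type microRNA expression with boolean expression calls."""

    values: pd.DataFrame                 # samples × microRNAs
    cell_of_sample: pd.Series            # sample_id -> cell type
    calls: pd.DataFrame                  # cell types × microRNAs (bool)
    max_expr: pd.DataFrame               # cell types × microRNAs
    mean_expr: pd.DataFrame              # cell types × microRNAs
    sample_counts: pd.Series             # cell type -> n samples
    expression_threshold: float = DEFAULT_THRESHOLD
    noise_floor: float = DEFAULT_NOISE_FLOOR
    hematopoietic: frozenset[str] = frozenset()
    contamination: dict[str, str] = field(default_factory=dict)
    #: Tissue-level evidence hook: tissue label -> accessions expressed there
    #: (e.g. placenta for the miR-517 family); metadata, never alters calls.
    tissue_expression: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(self.calls.index)

    @property
    def mirnas(self) -> list[str]:
        return list(self.calls.columns)

    def __contains__(self, accession: str) -> bool:
        return accession in self.calls.columns

    def write_values_tsv(self, path: str | Path) -> None:
        """microRNA rows × cell-type columns, 6 decimals (atlas-table layout).

        Writes the per-cell max, the summary the call rule is defined on, so
        an atlas reloaded from this file reproduces the calls exactly.
        """
        self.max_expr.T.round(6).to_csv(path, sep="\t")

    def write_calls_tsv(self, path: str | Path) -> None:
        self.calls.T.astype(int).to_csv(path, sep="\t")


@dataclass(frozen=True)
class ExpressedCells:
    """Result of an expressed-cells query; absence from the atlas is a
    distinguished no-data state, not an empty set."""

    cells: frozenset[str] | None
    count: int | None

    @property
    def no_data(self) -> bool:
        return self.cells is None


def build_atlas(
    m: SampleMatrix,
    cell_labels: Sequence | pd.Series | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    *,
    call_rule: str = "any",
    hematopoietic: Sequence[str] | None = None,
    contamination: Mapping[str, str] | None = None,
    tissue_expression: Mapping[str, Sequence[str]] | None = None,
    expected_cell_types: Sequence[str] | None = None,
) -> CellAtlas:
    """Group a normalized, batch-adjusted matrix into a cell atlas.

    ``call_rule="any"`` (default) calls a microRNA expressed in a cell when
    the max over that cell's samples is >= threshold (inclusive).
    ``call_rule="mean"`` is an experimental alternative using the per-cell
    mean.  ``expected_cell_types`` lets callers assert coverage; a declared
    cell type with zero samples is an error.
    """
    if cell_labels is None:
        cells = m.sample_meta["label"].astype(str)
    else:
        cells = pd.Series([str(c) for c in cell_labels], index=m.values.index)
    counts = cells.value_counts()
    if expected_cell_types is not None:
        empty = [c for c in expected_cell_types if counts.get(str(c), 0) == 0]
        if empty:
            raise ValueError(f"cell types with zero samples: {empty}")
    if call_rule not in {"any", "mean"}:
        raise ValueError(f"unknown call_rule {call_rule!r}")

    grouped = m.values.groupby(cells, sort=True)
    max_expr = grouped.max()
    mean_expr = grouped.mean()
    basis = max_expr if call_rule == "any" else mean_expr
    calls = basis >= threshold
    calls &= basis.notna()  # all-missing cells are not calls
    return CellAtlas(
        values=m.values.copy(),
        cell_of_sample=cells,
        calls=calls,
        max_expr=max_expr,
        mean_expr=mean_expr,
        sample_counts=counts.reindex(calls.index),
        expression_threshold=threshold,
        noise_floor=noise_floor,
        hematopoietic=frozenset(map(str, hematopoietic or ())),
        contamination=dict(contamination or {}),
        tissue_expression={
            t: frozenset(map(str, accs))
            for t, accs in (tissue_expression or {}).items()
        },
    )


def expressed_cells(atlas: CellAtlas, mirna: MirnaId | str) -> ExpressedCells:
    """Cells in which a microRNA is called expressed, with their count.

    Accepts a :class:`MirnaId` or a bare accession.  A microRNA absent from
    the atlas yields the no-data result.
    """
    acc = mirna.accession if isinstance(mirna, MirnaId) else str(mirna)
    if acc not in atlas.calls.columns:
        return ExpressedCells(cells=None, count=None)
    col = atlas.calls[acc]
    cells = frozenset(col.index[col])
    return ExpressedCells(cells=cells, count=len(cells))


@dataclass
class ClusterResult:
    """Agglomerative clustering of cell types on mean expression profiles."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the cell types into ``k`` flat clusters."""
        assign = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))


def cluster_cells(
    atlas: CellAtlas, *, distance: str = "correlation", linkage: str = "average"
) -> ClusterResult:
    """Cluster cell types by 1 − Pearson correlation of mean profiles.

    Only microRNAs with complete (non-missing) means across all cell types
    are used.  Deterministic; a zero-variance cell profile is an error
    because its correlation is undefined.
    """
    profiles = atlas.mean_expr.dropna(axis=1)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 cell types to cluster")
    variances = profiles.var(axis=1, ddof=0)
    flat = list(variances.index[variances == 0])
    if flat:
        raise ValueError(f"zero-variance cell profiles (correlation undefined): {flat}")
    X = profiles.to_numpy(dtype=float)
    if distance == "correlation":
        corr = np.corrcoef(X)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2, 0.0, None)
        condensed = d[np.triu_indices_from(d, k=1)]
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(X)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Zl = sch.linkage(condensed, method=linkage)
    labels = list(profiles.index)
    order = [labels[i] for i in sch.leaves_list(Zl)]
    return ClusterResult(linkage=Zl, labels=labels, leaf_order=order)


def read_atlas_values(
    path: str | Path,
    threshold: float = DEFAULT_THRESHOLD,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    **kwargs,
) -> CellAtlas:
    """Load an atlas from the values-TSV layout (microRNA rows × cell columns).

    Each cell type carries a single summary value per microRNA, so calls
    reduce to value >= threshold; the layout matches this module's
    ``write_values_tsv`` and published per-cell expression tables.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    cells_by_mirnas = df.T  # cell types × microRNAs
    samples = cells_by_mirnas.copy()
    samples.index = [f"{c}__s1" for c in cells_by_mirnas.index]
    meta = pd.DataFrame(
        {
            "label": list(cells_by_mirnas.index),
            "platform_version": "atlas",
            "batch_id": "atlas",
        },
        index=samples.index,
    )
    sm = SampleMatrix(samples, meta)
    return build_atlas(sm, threshold=threshold, noise_floor=noise_floor, **kwargs)
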