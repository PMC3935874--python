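"""Read probe-level expression tables, filter poor arrays, collapse probes.

Input files follow the GEO series-matrix convention: a TSV with one probe
per row and one sample per column, values on the log2 scale.  Arrays with
more than half their data missing (typically failed hybridizations or
corrupted submissions) are dropped, and probes are collapsed onto stable
MIMAT accessions via the nomenclature key so that matrices from different
platform versions share a feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .nomenclature import NomenclatureKey, UnknownMirnaError, harmonize

__all__ = [
    "SampleMatrix",
    "PlatformManifest",
    "read_sample_matrix",
    "read_manifest",
    "filter_missing_arrays",
    "collapse_probes",
]

logger = logging.getLogger(__name__)

#: Cell contents recognized as missing (case-insensitive), besides empty cells.
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

META_COLUMNS = ("label", "platform_version", "batch_id")


@dataclass
class SampleMatrix:
    """Samples × features log2 intensity matrix plus per-sample metadata.

    ``values``: DataFrame indexed by sample_id, columns are feature ids
    (probe names before collapsing, MIMAT accessions after), NaN marks
    missing.  ``sample_meta``: DataFrame indexed by sample_id with columns
    ``label`` (cell type or tissue), ``platform_version``, ``batch_id``
    (chip) and optionally ``compartment_class`` (cell|tissue).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta must share the sample index")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        missing_cols = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing_cols:
            raise ValueError(f"sample_meta lacks required columns {missing_cols}")
        with np.errstate(invalid="ignore"):
            vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("values must be finite where non-missing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-sample fraction of missing values over this matrix's features."""
        return self.values.isna().mean(axis=1)


@dataclass
class PlatformManifest:
    """Maps a platform version's probe names to microRNA names."""

    platform_version: str
    probe_to_name: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.probe_to_name)) != len(self.probe_to_name):
            raise ValueError("probe names must be unique within a platform")


def read_manifest(path: str | Path, platform_version: str) -> PlatformManifest:
    """Read a two-column TSV (probe TAB microRNA name) manifest."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "name"], dtype=str)
    if df["probe"].duplicated().any():
        dupes = df.loc[df["probe"].duplicated(), "probe"].tolist()
        raise ValueError(f"duplicate probes in manifest: {dupes[:5]}")
    return PlatformManifest(platform_version, dict(zip(df["probe"], df["name"])))


def _parse_cell(raw: object, row: str, col: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text.casefold() in MISSING_TOKENS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"non-numeric value {text!r} at feature {row!r}, sample {col!r}"
        ) from None


def read_sample_matrix(
    path: str | Path,
    manifest: PlatformManifest | None,
    meta: pd.DataFrame | Mapping[str, Mapping[str, object]] | str | Path,
    *,
    transpose: bool = False,
    log2_transform: bool = False,
) -> SampleMatrix:
    """Read a series-matrix-style TSV (features × samples) into a SampleMatrix.

    Parameters
    ----------
    manifest
        Optional platform manifest; when given, features absent from the
        manifest are kept (collapsing handles them) but a mismatch of every
        feature is an error, catching swapped files.
    meta
        Per-sample annotations: DataFrame indexed by sample_id, a mapping
        sample_id -> record, or a path to a TSV with a ``sample_id`` column.
    transpose
        Set when the file is oriented samples × features.
    log2_transform
        Apply log2 to the (linear-scale) values after parsing.  Default
        assumes the file is already on the log2 scale.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        raw = raw.T
    parsed = pd.DataFrame(
        {
            col: [_parse_cell(v, idx, col) for idx, v in series.items()]
            for col, series in raw.items()
        },
        index=raw.index,
        dtype=float,
    )
    if log2_transform:
        parsed = np.log2(parsed)

    if isinstance(meta, (str, Path)):
        meta = pd.read_csv(meta, sep="\t", dtype=str).set_index("sample_id")
    elif not isinstance(meta, pd.DataFrame):
        meta = pd.DataFrame.from_dict(meta, orient="index")
        meta.index.name = "sample_id"

    unannotated = [s for s in parsed.columns if s not in meta.index]
    if unannotated:
        raise ValueError(f"samples without metadata: {unannotated}")
    meta = meta.loc[list(parsed.columns)]

    if manifest is not None:
        known = sum(f in manifest.probe_to_name for f in parsed.index)
        if known == 0:
            raise ValueError(
                f"no feature of {path} is present in the "
                f"{manifest.platform_version} manifest"
            )
    return SampleMatrix(values=parsed.T, sample_meta=meta.copy())


def filter_missing_arrays(
    m: SampleMatrix, max_missing_fraction: float = 0.5
) -> SampleMatrix:
    """Drop samples whose missing fraction strictly exceeds the threshold.

    The threshold is strict (">"), so an array that is exactly half missing
    survives.  Survivor order is preserved; dropped sample ids are logged.
    Raises if every sample would be dropped.
    """
    if not 0.0 < max_missing_fraction < 1.0:
        raise ValueError("max_missing_fraction must lie strictly in (0, 1)")
    frac = m.missing_fraction()
    keep = frac <= max_missing_fraction
    dropped = list(frac.index[~keep])
    if dropped:
        logger.info(
            "filter_missing_arrays: dropped %d/%d samples: %s",
            len(dropped), m.n_samples, dropped,
        )
    if not keep.any():
        raise ValueError("all samples exceed the missing-data threshold")
    return SampleMatrix(m.values.loc[keep], m.sample_meta.loc[keep])


def collapse_probes(
    m: SampleMatrix, manifest: PlatformManifest, key: NomenclatureKey
) -> SampleMatrix:
    """Collapse probe-level features to MIMAT accessions.

    Probe -> name via the platform manifest, name -> accession via the
    nomenclature key.  Multiple probes mapping to one accession are combined
    by per-sample median of non-missing values (robust to one aberrant
    probe).  Probes with no manifest entry or an unresolvable name are
    dropped and logged; zero resolvable probes is an error.
    """
    accession_of: dict[str, str] = {}
    dropped: list[str] = []
    for probe in m.values.columns:
        name = manifest.probe_to_name.get(probe)
        if name is None:
            dropped.append(probe)
            continue
        try:
            accession_of[probe] = harmonize(name, key).accession
        except UnknownMirnaError:
            dropped.append(probe)
    if not accession_of:
        raise ValueError("no probe resolved to a MIMAT accession")
    if dropped:
        logger.info(
            "collapse_probes: dropped %d unresolvable probes: %s%s",
            len(dropped), dropped[:10], "..." if len(dropped) > 10 else "",
        )
    kept = m.values[list(accession_of)]
    collapsed = kept.T.groupby(kept.columns.map(accession_of)).median().T
    return SampleMatrix(collapsed, m.sample_meta.copy())
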