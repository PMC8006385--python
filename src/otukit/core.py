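"""Coordinated multi-assay container for microbial count data.

The central object is :class:`MicrobiomeExperiment`: a raw read-count matrix
(features x samples) kept in lockstep with an optional per-feature taxonomy
table and a per-sample metadata table. All subsetting goes through
:func:`pick_samples` / :func:`pick_features`, which preserve the alignment
invariants; derived abundance scales (relative abundance, logCPM) are computed
on demand through :func:`get_assay`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical taxonomic ranks, coarsest to finest.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Explicit marker for a missing taxonomy assignment.
UNCLASSIFIED = "unclassified"

#: A metadata column is continuous iff numeric with more than this many
#: distinct values; otherwise it is treated as categorical.
CONTINUOUS_DISTINCT_THRESHOLD = 8


class AssayKind(str, enum.Enum):
    """Closed set of abundance scales derivable from raw counts."""

    counts = "counts"
    relabu = "relabu"
    logcpm = "logcpm"


@dataclass(frozen=True)
class TaxonomyTable:
    """Per-feature lineage across the canonical ordered rank list.

    ``data`` is a features x ranks DataFrame whose columns are a subset of
    :data:`RANKS` in canonical order; entries are non-empty label strings,
    with :data:`UNCLASSIFIED` marking missing assignments.
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TaxonomyTable":
        """Normalize an arbitrary lineage frame: case-fold and reorder rank
        columns canonically, map blanks/NaN to the explicit missing marker."""
        rename = {}
        for col in frame.columns:
            key = str(col).strip().lower()
            if key not in RANKS:
                raise ValidationError(
                    f"unrecognized taxonomy rank column {col!r}; "
                    f"expected a subset of {RANKS}"
                )
            rename[col] = key
        frame = frame.rename(columns=rename)
        if frame.columns.duplicated().any():
            dupes = frame.columns[frame.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxonomy rank columns: {dupes}")
        ordered = [r for r in RANKS if r in frame.columns]
        if not ordered:
            raise ValidationError("taxonomy table has no recognized rank columns")
        out = frame[ordered].astype(object).copy()
        for col in ordered:
            vals = out[col]
            vals = vals.where(~vals.isna(), UNCLASSIFIED)
            vals = vals.astype(str).str.strip()
            vals = vals.where(vals != "", UNCLASSIFIED)
            out[col] = vals
        return cls(out)

    @property
    def ranks(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    def reindex(self, ids: Iterable[str]) -> "TaxonomyTable":
        ids = pd.Index(ids)
        missing = ids.difference(self.data.index)
        if len(missing):
            raise ValidationError(
                f"taxonomy missing features: {sorted(map(str, missing))[:10]}"
            )
        return TaxonomyTable(self.data.loc[ids])


@dataclass(frozen=True)
class MicrobiomeExperiment:
    """Coordinated (counts, taxonomy, sample metadata) triple.

    Construct through :func:`create_experiment`, which validates and aligns
    the three tables. Instances are immutable; subsetting returns new objects.
    """

    counts: pd.DataFrame
    sample_metadata: pd.DataFrame
    taxonomy: Optional[TaxonomyTable] = None

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    # Ergonomic method forms of the module-level operations.
    def pick_samples(self, ids, mode="keep"):
        return pick_samples(self, ids, mode)

    def pick_features(self, ids, mode="keep"):
        return pick_features(self, ids, mode)

    def get_assay(self, kind):
        return get_assay(self, kind)

    def summary(self):
        return experiment_summary(self)

    def equals(self, other: "MicrobiomeExperiment") -> bool:
        if not self.counts.equals(other.counts):
            return False
        if not self.sample_metadata.equals(other.sample_metadata):
            return False
        if (self.taxonomy is None) != (other.taxonomy is None):
            return False
        if self.taxonomy is not None and not self.taxonomy.data.equals(
            other.taxonomy.data
        ):
            return False
        return True


def _coerce_integer_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate non-negative integral counts; accept floats integral to 1e-9."""
    values = counts.to_numpy()
    if values.size == 0:
        raise ValidationError("counts matrix is empty")
    try:
        numeric = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"counts contain non-numeric values: {exc}") from exc
    if np.isnan(numeric).any():
        i, j = np.argwhere(np.isnan(numeric))[0]
        raise ValidationError(
            f"count for feature {counts.index[i]!r}, sample "
            f"{counts.columns[j]!r} is missing"
        )
    if (numeric < 0).any():
        i, j = np.argwhere(numeric < 0)[0]
        raise ValidationError(
            f"negative count for feature {counts.index[i]!r}, sample "
            f"{counts.columns[j]!r}"
        )
    rounded = np.rint(numeric)
    off = np.abs(numeric - rounded) > 1e-9
    if off.any():
        i, j = np.argwhere(off)[0]
        raise ValidationError(
            f"non-integer count {numeric[i, j]!r} for feature "
            f"{counts.index[i]!r}, sample {counts.columns[j]!r}"
        )
    return pd.DataFrame(
        rounded.astype(np.int64), index=counts.index, columns=counts.columns
    )


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.duplicated().any():
        dupes = labels[labels.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:10]}")


def create_experiment(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame | TaxonomyTable | None = None,
    metadata: pd.DataFrame | None = None,
) -> MicrobiomeExperiment:
    """Validate and assemble a :class:`MicrobiomeExperiment`.

    Taxonomy and metadata rows are reordered to match the counts labels;
    every sample must appear in ``metadata`` and (when taxonomy is given)
    every feature in ``taxonomy``.
    """
    if not isinstance(counts, pd.DataFrame):
        raise ValidationError("counts must be a labelled DataFrame")
    counts = _coerce_integer_counts(counts)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    _check_unique(counts.index, "feature ids")
    _check_unique(counts.columns, "sample ids")

    if metadata is None:
        metadata = pd.DataFrame(index=counts.columns)
    metadata = metadata.copy()
    metadata.index = metadata.index.astype(str)
    _check_unique(metadata.index, "metadata sample ids")
    missing = counts.columns.difference(metadata.index)
    if len(missing):
        raise ValidationError(
            f"metadata missing samples: {sorted(map(str, missing))}"
        )
    metadata = metadata.loc[counts.columns]

    tax: Optional[TaxonomyTable] = None
    if taxonomy is not None:
        if not isinstance(taxonomy, TaxonomyTable):
            taxonomy = TaxonomyTable.from_frame(taxonomy)
        taxonomy.data.index = taxonomy.data.index.astype(str)
        _check_unique(taxonomy.data.index, "taxonomy feature ids")
        tax = taxonomy.reindex(counts.index)

    return MicrobiomeExperiment(counts=counts, sample_metadata=metadata, taxonomy=tax)


def _resolve_selection(
    universe: pd.Index, ids: Iterable[str], mode: Literal["keep", "discard"], what: str
) -> pd.Index:
    ids = pd.Index([str(i) for i in ids])
    unknown = ids.difference(universe)
    if len(unknown):
        raise ValidationError(
            f"unknown {what}: {sorted(map(str, unknown))}"
        )
    if mode == "keep":
        kept = universe[universe.isin(ids)]
    elif mode == "discard":
        kept = universe[~universe.isin(ids)]
    else:
        raise ValidationError(f"mode must be 'keep' or 'discard', got {mode!r}")
    if len(kept) == 0:
        raise ValidationError(f"empty selection: no {what} would remain")
    return kept


def pick_samples(
    exp: MicrobiomeExperiment,
    ids: Iterable[str],
    mode: Literal["keep", "discard"] = "keep",
) -> MicrobiomeExperiment:
    """Isolate (``keep``) or drop (``discard``) samples, keeping metadata aligned."""
    kept = _resolve_selection(exp.sample_ids, ids, mode, "sample ids")
    return MicrobiomeExperiment(
        counts=exp.counts[kept],
        sample_metadata=exp.sample_metadata.loc[kept],
        taxonomy=exp.taxonomy,
    )


def pick_features(
    exp: MicrobiomeExperiment,
    ids: Iterable[str],
    mode: Literal["keep", "discard"] = "keep",
) -> MicrobiomeExperiment:
    """Isolate or drop features, keeping taxonomy aligned."""
    kept = _resolve_selection(exp.feature_ids, ids, mode, "feature ids")
    tax = exp.taxonomy.reindex(kept) if exp.taxonomy is not None else None
    return MicrobiomeExperiment(
        counts=exp.counts.loc[kept],
        sample_metadata=exp.sample_metadata,
        taxonomy=tax,
    )


def get_assay(exp: MicrobiomeExperiment, kind: AssayKind | str) -> pd.DataFrame:
    """Return the requested abundance scale with labels preserved.

    ``counts`` is the stored matrix verbatim; ``relabu`` and ``logcpm`` are
    computed by the transform module.
    """
    kind = AssayKind(kind)
    if kind is AssayKind.counts:
        return exp.counts.copy()
    from . import transform

    if kind is AssayKind.relabu:
        return transform.counts_to_relabu(exp.counts)
    return transform.counts_to_logcpm(exp.counts)


@dataclass(frozen=True)
class ExperimentSummary:
    """Data-quality snapshot of an experiment."""

    n_features: int
    n_samples: int
    library_sizes: pd.Series
    feature_stats: pd.DataFrame  # mean_count, prevalence, mean_relabu
    covariate_types: dict[str, str] = field(default_factory=dict)


def covariate_type(values: pd.Series) -> str:
    """Classify a metadata column as ``continuous`` or ``categorical``.

    Continuous iff numeric with more than
    :data:`CONTINUOUS_DISTINCT_THRESHOLD` distinct non-null values.
    """
    numeric = pd.api.types.is_numeric_dtype(values) and not (
        pd.api.types.is_bool_dtype(values)
    )
    if numeric and values.dropna().nunique() > CONTINUOUS_DISTINCT_THRESHOLD:
        return "continuous"
    return "categorical"


def experiment_summary(exp: MicrobiomeExperiment) -> ExperimentSummary:
    """Per-sample library sizes, per-feature abundance stats, covariate census."""
    counts = exp.counts
    lib = counts.sum(axis=0).rename("library_size")
    mean_count = counts.mean(axis=1)
    prevalence = (counts > 0).mean(axis=1)
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        relabu = counts.to_numpy(dtype=float) / np.where(totals > 0, totals, np.nan)
    mean_relabu = pd.Series(
        np.nanmean(relabu, axis=1) if np.isfinite(relabu).any() else 0.0,
        index=counts.index,
    )
    stats = pd.DataFrame(
        {
            "mean_count": mean_count,
            "prevalence": prevalence,
            "mean_relabu": mean_relabu.fillna(0.0),
        }
    )
    types = {
        col: covariate_type(exp.sample_metadata[col])
        for col in exp.sample_metadata.columns
    }
    return ExperimentSummary(
        n_features=exp.n_features,
        n_samples=exp.n_samples,
        library_sizes=lib,
        feature_stats=stats,
        covariate_types=types,
    )
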