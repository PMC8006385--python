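"""Abundance transforms, taxonomy aggregation, filtering, and discretization.

Transforms operate on labelled count DataFrames (features x samples):

* relative abundance: each sample column divided by its library size;
* logCPM: ``log2(count * 1e6 / library_size + 1)`` — zeros map to 0 and the
  scale is invariant to library size.

Filtering follows a fixed pipeline order — sample filters first, then feature
criteria evaluated on the retained samples — because prevalence and mean
relative abundance depend on which samples remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    RANKS,
    UNCLASSIFIED,
    MicrobiomeExperiment,
    TaxonomyTable,
    covariate_type,
    create_experiment,
    experiment_summary,
    pick_samples,
)
from .errors import AnalysisError, ValidationError


def _library_sizes(matrix: pd.DataFrame) -> np.ndarray:
    lib = matrix.sum(axis=0).to_numpy(dtype=float)
    zero = np.flatnonzero(lib <= 0)
    if len(zero):
        bad = [str(matrix.columns[j]) for j in zero]
        raise AnalysisError(f"all-zero sample column(s): {bad}")
    return lib


def counts_to_relabu(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize counts to per-sample proportions (each column sums to 1)."""
    lib = _library_sizes(matrix)
    return matrix.astype(float).div(lib, axis=1)


def counts_to_logcpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) with per-sample library-size normalization."""
    lib = _library_sizes(matrix)
    cpm = matrix.astype(float).div(lib, axis=1) * 1e6
    return np.log2(cpm + 1.0)


def upsample_counts(exp: MicrobiomeExperiment, level: str) -> MicrobiomeExperiment:
    """Aggregate features to a coarser taxonomic rank by summing counts.

    Features sharing a label at ``level`` are summed; the new feature ids are
    the level labels (including the explicit ``unclassified`` bucket), and the
    taxonomy is truncated to ranks at or above ``level``. Column sums are
    conserved exactly.
    """
    if exp.taxonomy is None:
        raise ValidationError("cannot aggregate: experiment has no taxonomy")
    if level not in RANKS:
        raise ValidationError(f"unknown rank {level!r}; expected one of {RANKS}")
    if level not in exp.taxonomy.ranks:
        raise ValidationError(
            f"rank {level!r} not present in taxonomy (has {exp.taxonomy.ranks})"
        )
    labels = exp.taxonomy.data[level]
    grouped = exp.counts.groupby(labels, sort=False).sum()
    grouped.index.name = None

    keep_ranks = [r for r in exp.taxonomy.ranks if RANKS.index(r) <= RANKS.index(level)]
    lineage_rows = {}
    for label, sub in exp.taxonomy.data.groupby(labels, sort=False):
        row = {}
        for r in keep_ranks:
            uniq = sub[r].unique()
            row[r] = uniq[0] if len(uniq) == 1 else UNCLASSIFIED
        row[level] = label
        lineage_rows[label] = row
    tax = pd.DataFrame.from_dict(lineage_rows, orient="index")[keep_ranks]
    tax = tax.loc[grouped.index]

    return create_experiment(grouped, taxonomy=tax, metadata=exp.sample_metadata)


def counts_at_level(exp: MicrobiomeExperiment, level: str | None) -> pd.DataFrame:
    """Counts aggregated to ``level`` (or the raw feature level when None)."""
    if level is None:
        return exp.counts
    return upsample_counts(exp, level).counts


@dataclass(frozen=True)
class FilterSpec:
    """Conjunction of feature-retention criteria.

    A feature is kept iff its mean raw count, mean relative abundance, and
    prevalence all meet their thresholds and it is not explicitly discarded.
    """

    min_avg_reads: float = 0.0
    min_mean_relabu: float = 0.0
    min_prevalence: float = 0.0
    explicit_discard: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.min_avg_reads < 0:
            raise ValidationError("min_avg_reads must be >= 0")
        if not 0 <= self.min_mean_relabu <= 1:
            raise ValidationError("min_mean_relabu must be in [0, 1]")
        if not 0 <= self.min_prevalence <= 1:
            raise ValidationError("min_prevalence must be in [0, 1]")


def filter_features(
    exp: MicrobiomeExperiment, spec: FilterSpec
) -> tuple[MicrobiomeExperiment, pd.DataFrame]:
    """Apply a :class:`FilterSpec`; return the filtered experiment and a
    removal report (feature id, criterion failed, offending value)."""
    stats = experiment_summary(exp).feature_stats
    records = []
    keep = pd.Series(True, index=exp.feature_ids)
    for fid in exp.feature_ids:
        row = stats.loc[fid]
        if fid in spec.explicit_discard:
            records.append((fid, "explicit_discard", np.nan))
            keep[fid] = False
            continue
        if row["mean_count"] < spec.min_avg_reads:
            records.append((fid, "min_avg_reads", row["mean_count"]))
            keep[fid] = False
        elif row["mean_relabu"] < spec.min_mean_relabu:
            records.append((fid, "min_mean_relabu", row["mean_relabu"]))
            keep[fid] = False
        elif row["prevalence"] < spec.min_prevalence:
            records.append((fid, "min_prevalence", row["prevalence"]))
            keep[fid] = False
    report = pd.DataFrame(records, columns=["feature_id", "criterion", "value"])
    kept_ids = exp.feature_ids[keep.to_numpy()]
    if len(kept_ids) == 0:
        raise ValidationError("filter spec would remove every feature")
    if len(kept_ids) == exp.n_features:
        return exp, report
    return exp.pick_features(kept_ids, "keep"), report


def filter_samples(
    exp: MicrobiomeExperiment,
    covariate: str | None = None,
    equals=None,
    member_of=None,
    range_: tuple[float | None, float | None] | None = None,
    ids=None,
    mode: str = "keep",
) -> MicrobiomeExperiment:
    """Subset samples by a covariate predicate or an explicit id list.

    Exactly one of ``equals`` / ``member_of`` / ``range_`` (with ``covariate``)
    or ``ids`` must be given. Range predicates require a continuous covariate.
    """
    if ids is not None:
        return pick_samples(exp, ids, mode)
    if covariate is None:
        raise ValidationError("either a covariate predicate or explicit ids required")
    if covariate not in exp.sample_metadata.columns:
        raise ValidationError(f"unknown covariate {covariate!r}")
    col = exp.sample_metadata[covariate]
    given = [p is not None for p in (equals, member_of, range_)]
    if sum(given) != 1:
        raise ValidationError("exactly one predicate (equals/member_of/range_) required")
    if equals is not None:
        mask = col == equals
    elif member_of is not None:
        mask = col.isin(list(member_of))
    else:
        if covariate_type(col) != "continuous":
            raise ValidationError(
                f"range predicate requires a continuous covariate; {covariate!r} is not"
            )
        lo, hi = range_
        mask = pd.Series(True, index=col.index)
        if lo is not None:
            mask &= col >= lo
        if hi is not None:
            mask &= col <= hi
    kept = exp.sample_ids[mask.to_numpy()]
    if len(kept) == 0:
        raise ValidationError("sample predicate matched no samples")
    if len(kept) == exp.n_samples:
        return exp
    return pick_samples(exp, kept, "keep")


def categorize_covariate(
    values: pd.Series | np.ndarray,
    n_bins: int | None = None,
    breakpoints=None,
    equal_width: bool = False,
) -> tuple[pd.Series, list[str]]:
    """Discretize a continuous vector into labelled bins.

    Default is quantile (equal-count) binning; ``equal_width=True`` switches to
    equal-width bins; explicit ``breakpoints`` are honoured verbatim. Bins are
    half-open ``[lo, hi)`` with the final bin closed ``[lo, hi]``.
    """
    values = pd.Series(values)
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.isna().any() and not values.isna().any():
        raise ValidationError("categorize_covariate requires numeric input")
    x = numeric.to_numpy(dtype=float)

    if breakpoints is not None:
        edges = np.asarray(sorted(breakpoints), dtype=float)
        if len(edges) < 2 or len(np.unique(edges)) != len(edges):
            raise ValidationError("breakpoints must be >= 2 distinct values")
    else:
        if n_bins is None or n_bins < 2:
            raise ValidationError("n_bins must be an integer >= 2")
        distinct = np.unique(x[~np.isnan(x)])
        if len(distinct) < 2:
            raise ValidationError("cannot bin a constant vector")
        if n_bins > len(distinct):
            raise ValidationError(
                f"n_bins={n_bins} exceeds the {len(distinct)} distinct values"
            )
        if equal_width:
            edges = np.linspace(np.nanmin(x), np.nanmax(x), n_bins + 1)
        else:
            qs = np.linspace(0, 1, n_bins + 1)
            edges = np.nanquantile(x, qs)
        edges = np.unique(edges)
        if len(edges) < 2:
            raise ValidationError("degenerate bin edges (too many ties)")

    labels = []
    for i in range(len(edges) - 1):
        closer = "]" if i == len(edges) - 2 else ")"
        labels.append(f"[{edges[i]:g},{edges[i + 1]:g}{closer}")

    # right-open bins, final bin closed on the right
    idx = np.digitize(x, edges[1:-1], right=False)
    out_of_range = (x < edges[0]) | (x > edges[-1])
    cats = pd.Series(
        pd.Categorical(
            [labels[i] if not o and not np.isnan(v) else None
             for i, o, v in zip(idx, out_of_range, x)],
            categories=labels,
        ),
        index=values.index,
    )
    return cats, labels
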