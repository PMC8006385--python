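"""Alpha and beta diversity: metrics, group tests, and PERMANOVA.

Alpha metrics operate on per-sample proportion vectors ``p``:

* Shannon: ``-sum p_i ln p_i`` (zero terms contribute 0)
* Gini-Simpson: ``1 - sum p_i^2``
* Inverse Simpson: ``1 / sum p_i^2``
* richness: number of features with nonzero count

Beta diversity supports Bray-Curtis and binary Jaccard dissimilarities,
computed on relative abundance by default (Bray-Curtis) to remove the
library-size confound; Jaccard is always the presence/absence form on raw
counts. PERMANOVA partitions the squared-distance sums of squares between and
within groups and assesses the pseudo-F statistic against a label-permutation
null; the permutation p-value uses the ``(1 + b) / (1 + m)`` estimator so it
never returns exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AssayKind, MicrobiomeExperiment
from .errors import AnalysisError, ValidationError
from .transform import counts_at_level, counts_to_relabu

ALPHA_METRICS = ("shannon", "gini_simpson", "inverse_simpson", "richness")
BETA_METRICS = ("bray_curtis", "jaccard")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with a metric label."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValidationError("sample_ids length mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class TestResult:
    """Outcome of a univariate or distance-based statistical test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n_permutations: int | None = None

    def __post_init__(self):
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value out of range: {self.p_value}")


def alpha_diversity(
    exp: MicrobiomeExperiment,
    metric: str = "shannon",
    level: str | None = None,
) -> pd.Series:
    """Per-sample alpha diversity at a taxonomic level (raw features when None)."""
    if metric not in ALPHA_METRICS:
        raise ValidationError(f"unknown alpha metric {metric!r}; use {ALPHA_METRICS}")
    counts = counts_at_level(exp, level)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise AnalysisError(f"all-zero sample(s): {bad}")
    p = counts.to_numpy(dtype=float) / lib.to_numpy(dtype=float)
    if metric == "richness":
        vals = (counts.to_numpy() > 0).sum(axis=0).astype(float)
    elif metric == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        vals = -terms.sum(axis=0)
    else:
        simpson = (p**2).sum(axis=0)
        vals = 1.0 - simpson if metric == "gini_simpson" else 1.0 / simpson
    return pd.Series(vals, index=counts.columns, name=metric)


def _two_groups(values: pd.Series, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, got {len(levels)}")
    a = values[groups == levels[0]].to_numpy(dtype=float)
    b = values[groups == levels[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    return a, b


def alpha_div_test(
    values: pd.Series, groups: Sequence, method: str = "wilcoxon"
) -> TestResult:
    """Compare per-sample diversity values across groups.

    ``wilcoxon`` is the two-sided rank-sum test (exact enumeration when both
    groups have <= 8 tie-free observations, otherwise the tie-corrected normal
    approximation with continuity correction); ``t_test`` is Welch's unequal
    variance t; ``kruskal_wallis`` is the tie-corrected H test.
    """
    values = pd.Series(values)
    groups = pd.Series(list(groups), index=values.index)
    if method == "wilcoxon":
        a, b = _two_groups(values, groups)
        tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        exact = tie_free and len(a) <= 8 and len(b) <= 8
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
        return TestResult(float(res.statistic), float(res.pvalue),
                          "wilcoxon_exact" if exact else "wilcoxon_normal")
    if method == "t_test":
        a, b = _two_groups(values, groups)
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(float(res.statistic), float(res.pvalue), "welch_t",
                          df=float(res.df))
    if method == "kruskal_wallis":
        levels = pd.unique(groups)
        if len(levels) < 2:
            raise ValidationError("kruskal_wallis needs >= 2 groups")
        samples = [values[groups == g].to_numpy(dtype=float) for g in levels]
        if any(len(s) < 2 for s in samples):
            raise ValidationError("each group needs at least 2 observations")
        if np.ptp(np.concatenate(samples)) == 0:
            # all values identical: H is 0 by definition, no separation
            return TestResult(0.0, 1.0, "kruskal_wallis", df=float(len(levels) - 1))
        res = sps.kruskal(*samples)
        return TestResult(float(res.statistic), float(res.pvalue), "kruskal_wallis",
                          df=float(len(levels) - 1))
    raise ValidationError(f"unknown method {method!r}")


def _bray_curtis(X: np.ndarray) -> np.ndarray:
    # X: samples x features
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        tot = (X[i] + X[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / tot, np.nan)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


def _jaccard(present: np.ndarray) -> np.ndarray:
    n = present.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        inter = (present[i] & present[i + 1:]).sum(axis=1)
        union = (present[i] | present[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(union > 0, 1.0 - inter / union, np.nan)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


def beta_distance(
    data: MicrobiomeExperiment | pd.DataFrame,
    metric: str = "bray_curtis",
    assay: AssayKind | str = AssayKind.relabu,
    level: str | None = None,
) -> DistanceMatrix:
    """Pairwise sample dissimilarities.

    Bray-Curtis is computed on the requested assay (relative abundance by
    default); Jaccard is the binary presence/absence index on raw counts.
    """
    if metric not in BETA_METRICS:
        raise ValidationError(f"unknown beta metric {metric!r}; use {BETA_METRICS}")
    if isinstance(data, MicrobiomeExperiment):
        counts = counts_at_level(data, level)
    else:
        counts = data
    if counts.shape[1] < 2:
        raise ValidationError("beta diversity requires >= 2 samples")
    sample_ids = tuple(str(c) for c in counts.columns)
    if metric == "jaccard":
        D = _jaccard((counts.to_numpy() > 0).T)
    else:
        kind = AssayKind(assay)
        if kind is AssayKind.relabu:
            mat = counts_to_relabu(counts)
        else:
            mat = counts.astype(float)
        D = _bray_curtis(mat.to_numpy(dtype=float).T)
    if np.isnan(D).any():
        i, j = np.argwhere(np.isnan(D))[0]
        raise AnalysisError(
            f"distance undefined between all-zero samples "
            f"{sample_ids[i]!r} and {sample_ids[j]!r}"
        )
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, sample_ids, metric)


def beta_group_distances(
    D: DistanceMatrix, groups: Sequence
) -> dict[str, np.ndarray]:
    """Partition strict upper-triangle distances into within-group-1,
    within-group-2, and between-group pair values (two-level grouping)."""
    groups = np.asarray(list(groups))
    if len(groups) != D.n:
        raise ValidationError("groups length must match the distance matrix")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, got {len(levels)}")
    g1, g2 = levels
    if (groups == g1).sum() < 2 or (groups == g2).sum() < 2:
        raise ValidationError("each group needs at least 2 samples")
    iu, ju = np.triu_indices(D.n, k=1)
    pair_vals = D.values[iu, ju]
    a, b = groups[iu], groups[ju]
    return {
        "within_g1": pair_vals[(a == g1) & (b == g1)],
        "within_g2": pair_vals[(a == g2) & (b == g2)],
        "between": pair_vals[a != b],
        "labels": np.array([str(g1), str(g2)], dtype=object),
    }


def _permanova_f(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes."""
    N = D2.shape[0]
    ss_t = D2.sum() / (2.0 * N)
    ss_w = 0.0
    for g in range(n_groups):
        mask = (codes == g).astype(float)
        n_g = mask.sum()
        if n_g < 2:
            continue
        ss_w += (mask @ D2 @ mask) / (2.0 * n_g)
    a = n_groups
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (N - a))


def _permanova_f_batch(D2: np.ndarray, codes_batch: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for a batch of labelings (rows of ``codes_batch``)."""
    N = D2.shape[0]
    ss_t = D2.sum() / (2.0 * N)
    ss_w = np.zeros(codes_batch.shape[0])
    for g in range(n_groups):
        M = (codes_batch == g).astype(float)
        n_g = M[0].sum()  # group sizes are permutation-invariant
        if n_g < 2:
            continue
        ss_w += ((M @ D2) * M).sum(axis=1) / (2.0 * n_g)
    a = n_groups
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (N - a))


def permanova(
    D: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Total sum of squares ``SS_T = (1/N) sum_{i<j} d_ij^2``; within-group
    ``SS_W = sum_g (1/n_g) sum_{i<j in g} d_ij^2``; pseudo-F compares the
    between to within mean squares, and the p-value counts permuted labelings
    with ``F_perm >= F_obs`` using the (1+b)/(1+m) estimator.
    """
    if seed is None:
        raise ValidationError("permanova requires an explicit seed")
    groups = np.asarray(list(groups))
    if len(groups) != D.n:
        raise ValidationError("groups length must match the distance matrix")
    levels, codes = np.unique(groups, return_inverse=True)
    a = len(levels)
    if a < 2:
        raise ValidationError("permanova needs >= 2 groups")
    if D.n < a + 1:
        raise ValidationError("permanova needs N >= number of groups + 1")
    sizes = np.bincount(codes)
    if (sizes == 1).any():
        warnings.warn(
            "singleton group in PERMANOVA: its within-group term is zero",
            stacklevel=2,
        )
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is very small; p resolution is coarse",
                      stacklevel=2)
    D2 = D.values**2
    f_obs = _permanova_f(D2, codes, a)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, D.n), dtype=codes.dtype)
    for i in range(n_perm):
        perms[i] = rng.permutation(codes)
    f_perm = _permanova_f_batch(D2, perms, a)
    b = int((f_perm >= f_obs - 1e-12).sum())
    p = (1.0 + b) / (1.0 + n_perm)
    return TestResult(float(f_obs), float(p), "permanova", df=float(a - 1),
                      n_permutations=n_perm)


def beta_div_test(
    D: DistanceMatrix,
    groups: Sequence,
    method: str = "permanova",
    n_perm: int = 999,
    seed: int | None = None,
) -> TestResult:
    """Distance-based group test.

    ``permanova`` delegates to :func:`permanova`; ``wilcoxon`` and
    ``kruskal_wallis`` compare pooled within-group versus between-group
    distances from :func:`beta_group_distances`.
    """
    if method == "permanova":
        return permanova(D, groups, n_perm=n_perm, seed=seed)
    parts = beta_group_distances(D, groups)
    within = np.concatenate([parts["within_g1"], parts["within_g2"]])
    between = parts["between"]
    vals = pd.Series(np.concatenate([within, between]))
    labels = pd.Series(["within"] * len(within) + ["between"] * len(between))
    if method in ("wilcoxon", "kruskal_wallis"):
        return alpha_div_test(vals, labels, method=method)
    raise ValidationError(f"unknown method {method!r}")
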