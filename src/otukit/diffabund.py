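"""Two-path differential abundance for two-group microbiome designs.

Path 1 (``nb_wald``) models raw counts per feature with a negative-binomial
GLM (log link, mean/dispersion parameterization ``Var = mu + alpha mu^2``),
library-size offsets from median-of-ratios size factors, per-feature
dispersion by bounded maximum likelihood, and a Wald test on the group
coefficient. This is DESeq2-style in spirit — median-of-ratios normalization
plus an NB Wald test — but deliberately fits dispersions without shrinkage
toward a trend, so numerical equality with DESeq2 is not expected.

Path 2 (``moderated_t``) fits ordinary least squares to logCPM values and
moderates the per-feature residual variances with the classic empirical-Bayes
scaled-inverse-chi-square prior: hyperparameters ``(d0, s0^2)`` are estimated
by moment matching of ``log s_g^2`` (digamma/trigamma inversion), posterior
variances are ``(d0 s0^2 + d_g s_g^2) / (d0 + d_g)``, and the moderated t has
``d0 + d_g`` degrees of freedom.

Both paths report the extended per-feature columns: group mean relative
abundance ("percentage"), group prevalence, and an epsilon-stabilized
group-size-adjusted fold change, with Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import MicrobiomeExperiment, covariate_type
from .errors import AnalysisError, ValidationError
from .transform import counts_to_logcpm, counts_to_relabu, upsample_counts

#: Stabilizer for the group-size-adjusted fold change.
ADJ_FC_EPSILON = 1e-6

#: Dispersion search bounds for the NB maximum-likelihood fit.
DISPERSION_BOUNDS = (1e-8, 10.0)


@dataclass(frozen=True)
class DAConfig:
    """Configuration for a differential-abundance run.

    ``target`` must be a two-level categorical covariate; the tested effect is
    level2 vs level1 (levels in first-appearance order). ``min_count`` filters
    features by mean raw count across all samples before testing.
    """

    target: str
    method: str = "nb_wald"
    level: str | None = None
    covariates: tuple[str, ...] = field(default_factory=tuple)
    min_count: float = 1.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.method not in ("nb_wald", "moderated_t"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.min_count < 0:
            raise ValidationError("min_count must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# normalization

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Zero-tolerant median-of-ratios sample normalization factors.

    The per-feature geometric mean is taken over strictly positive counts
    only; each sample's factor is the median ratio ``c_ij / geomean_i`` over
    features positive in that sample, rescaled so the factors have geometric
    mean 1.
    """
    mat = counts.to_numpy(dtype=float)
    pos = mat > 0
    logs = np.log(mat, out=np.zeros_like(mat, dtype=float), where=pos)
    npos = pos.sum(axis=1)
    usable = npos > 0
    geo = np.full(mat.shape[0], np.nan)
    geo[usable] = np.exp(logs[usable].sum(axis=1) / npos[usable])
    factors = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        mask = pos[:, j] & usable
        if not mask.any():
            raise AnalysisError(
                f"sample {counts.columns[j]!r} shares no positive feature "
                "with the geometric-mean reference"
            )
        factors[j] = np.median(mat[mask, j] / geo[mask])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB-Wald path

def _nb_negloglik(y, mu, alpha):
    r = 1.0 / alpha
    return -np.sum(
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _nb_cr_negloglik(y, mu, alpha, X):
    """Cox-Reid adjusted profile likelihood for the dispersion.

    The +0.5 log det(X'WX) term removes the downward bias the fitted mean
    parameters induce in the plain dispersion MLE (anticonservative Wald
    tests otherwise).
    """
    W = mu / (1.0 + alpha * mu)
    sign, logdet = np.linalg.slogdet((X.T * W) @ X)
    if sign <= 0:
        return np.inf
    return _nb_negloglik(y, mu, alpha) + 0.5 * logdet

def _nb_irls(y, X, offset, alpha, beta0=None, max_iter=50, tol=1e-8):
    """Fit NB GLM coefficients by iteratively reweighted least squares."""
    n, p = X.shape
    if beta0 is None:
        # Poisson-like start from log mean rates
        rate = np.log((y.sum() + 0.5) / np.exp(offset).sum())
        beta = np.zeros(p)
        beta[0] = rate
    else:
        beta = beta0.copy()
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = eta - offset + (y - mu) / mu
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, mu, False
        if not np.all(np.isfinite(beta_new)):
            return beta, mu, False
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            eta = np.clip(X @ beta + offset, -30, 30)
            return beta, np.exp(eta), True
    eta = np.clip(X @ beta + offset, -30, 30)
    return beta, np.exp(eta), False


def _fit_nb_feature(y, X, offset):
    """Profile out the dispersion: alternate IRLS for beta and bounded ML for
    alpha, starting from a method-of-moments dispersion estimate."""
    lo, hi = DISPERSION_BOUNDS
    mu0 = np.exp(np.clip(offset + np.log((y.mean() + 0.5) / np.exp(offset).mean()), -30, 30))
    mom = (np.var(y, ddof=1) - mu0.mean()) / max(mu0.mean() ** 2, 1e-12)
    alpha = float(np.clip(mom if np.isfinite(mom) else 0.1, lo, hi))
    beta = None
    converged = False
    for _ in range(8):
        beta, mu, ok = _nb_irls(y, X, offset, alpha, beta0=beta)
        res = optimize.minimize_scalar(
            lambda a: _nb_cr_negloglik(y, mu, a, X),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        new_alpha = float(res.x)
        done = ok and abs(np.log(new_alpha / alpha)) < 1e-4
        alpha = new_alpha
        if done:
            converged = True
            break
    beta, mu, ok = _nb_irls(y, X, offset, alpha, beta0=beta)
    converged = converged and ok
    W = mu / (1.0 + alpha * mu)
    info = (X.T * W) @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        converged = False
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        converged = False
    return beta, se, alpha, converged


def _design_matrix(exp: MicrobiomeExperiment, config: DAConfig):
    meta = exp.sample_metadata
    if config.target not in meta.columns:
        raise ValidationError(f"unknown target covariate {config.target!r}")
    target = meta[config.target]
    levels = pd.unique(target)
    if len(levels) != 2:
        raise ValidationError(
            f"target {config.target!r} must have exactly 2 levels, got {len(levels)}"
        )
    cols = [np.ones(len(meta)), (target == levels[1]).to_numpy(dtype=float)]
    names = ["intercept", f"{config.target}[{levels[1]}]"]
    for cov in config.covariates:
        if cov not in meta.columns:
            raise ValidationError(f"unknown covariate {cov!r}")
        col = meta[cov]
        if covariate_type(col) == "continuous":
            v = col.to_numpy(dtype=float)
            cols.append((v - v.mean()) / (v.std(ddof=0) or 1.0))
            names.append(cov)
        else:
            sub = pd.unique(col)
            for lev in sub[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    return X, names, levels, target


def da_extended_columns(
    exp: MicrobiomeExperiment, target: str, level: str | None = None
) -> pd.DataFrame:
    """Group percentage (mean relative abundance), prevalence, and adjusted FC."""
    if level is not None:
        exp = upsample_counts(exp, level)
    tgt = exp.sample_metadata[target]
    levels = pd.unique(tgt)
    if len(levels) != 2:
        raise ValidationError(f"target {target!r} must have exactly 2 levels")
    relabu = counts_to_relabu(exp.counts)
    g1 = tgt == levels[0]
    g2 = tgt == levels[1]
    pct1 = relabu.loc[:, g1.to_numpy()].mean(axis=1)
    pct2 = relabu.loc[:, g2.to_numpy()].mean(axis=1)
    prev1 = (exp.counts.loc[:, g1.to_numpy()] > 0).mean(axis=1)
    prev2 = (exp.counts.loc[:, g2.to_numpy()] > 0).mean(axis=1)
    adj_fc = (pct1 + ADJ_FC_EPSILON) / (pct2 + ADJ_FC_EPSILON)
    return pd.DataFrame(
        {
            "pct_group1": pct1,
            "pct_group2": pct2,
            "prev_group1": prev1,
            "prev_group2": prev2,
            "adj_fc": adj_fc,
        }
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg over non-missing entries; NaN stays NaN."""
    out = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _assemble_result(exp, config, feature_ids, log2fc, se, stat, p, extra_cols, flags):
    p_adj = _bh_adjust(p)
    extended = da_extended_columns(exp, config.target, level=None).loc[feature_ids]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "statistic": stat,
            "p": p,
            "p_adj": p_adj,
        },
        index=feature_ids,
    )
    table = pd.concat([table, extended], axis=1)
    for k, v in extra_cols.items():
        table[k] = v
    table["converged"] = flags
    table.index.name = "feature_id"
    return table.sort_values("p", kind="stable")


def _prepare(exp: MicrobiomeExperiment, config: DAConfig):
    if config.level is not None:
        exp = upsample_counts(exp, config.level)
    keep = exp.counts.mean(axis=1) >= config.min_count
    if keep.sum() == 0:
        raise AnalysisError("no feature passes the min_count filter")
    exp = exp.pick_features(exp.feature_ids[keep.to_numpy()], "keep")
    return exp


def da_nb_wald(exp: MicrobiomeExperiment, config: DAConfig) -> pd.DataFrame:
    """Negative-binomial Wald differential abundance (DESeq2-style)."""
    exp = _prepare(exp, config)
    X, names, levels, _ = _design_matrix(exp, config)
    sf = size_factors(exp.counts)
    offset = np.log(sf.to_numpy())
    Y = exp.counts.to_numpy(dtype=float)
    n_feat = Y.shape[0]
    log2fc = np.full(n_feat, np.nan)
    se_out = np.full(n_feat, np.nan)
    stat = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    disp = np.full(n_feat, np.nan)
    flags = np.zeros(n_feat, dtype=bool)
    for i in range(n_feat):
        beta, se, alpha_hat, ok = _fit_nb_feature(Y[i], X, offset)
        disp[i] = alpha_hat
        if not ok:
            continue
        flags[i] = True
        z = beta[1] / se[1]
        log2fc[i] = beta[1] / np.log(2.0)
        se_out[i] = se[1] / np.log(2.0)
        stat[i] = z
        p[i] = 2.0 * sps.norm.sf(abs(z))
    n_fail = int((~flags).sum())
    if n_fail:
        warnings.warn(f"{n_fail} feature(s) failed to converge; excluded from BH",
                      stacklevel=2)
    return _assemble_result(
        exp, config, exp.feature_ids, log2fc, se_out, stat, p,
        {"dispersion": disp, "method": "nb_wald",
         "contrast": f"{levels[1]} vs {levels[0]}"},
        flags,
    )


# ---------------------------------------------------------------------------
# moderated-t path

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled-inverse-chi-square variance prior.

    Returns ``(d0, s0_sq)``; ``d0`` is ``inf`` when the observed spread of
    ``log s_g^2`` is no larger than expected from chi-square sampling alone.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise AnalysisError("too few positive residual variances for EB fit")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_t_fit(
    Y: np.ndarray, X: np.ndarray, coef: int = 1, d0_override: float | None = None
) -> pd.DataFrame:
    """Empirical-Bayes moderated t for each row of ``Y`` against design ``X``.

    ``Y`` is features x samples on a Gaussian-like scale (logCPM).
    ``d0_override`` forces the prior df (0 -> ordinary t; inf -> pooled
    variance), mainly for diagnostics.
    """
    n, p_dim = X.shape
    if Y.shape[1] != n:
        raise ValidationError("Y columns must match design rows")
    df_res = n - p_dim
    if df_res < 1:
        raise AnalysisError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    B = Y @ H.T  # features x p coefficients
    fitted = B @ X.T
    resid = Y - fitted
    s2 = (resid**2).sum(axis=1) / df_res
    v = XtX_inv[coef, coef]
    if d0_override is not None:
        d0 = float(d0_override)
        if np.isinf(d0):
            s0_sq = float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300)))))
        else:
            s0_sq = float(s2.mean())
    else:
        try:
            d0, s0_sq = estimate_variance_prior(s2, df_res)
        except AnalysisError:
            warnings.warn("EB prior estimation failed; pooling variances",
                          stacklevel=2)
            d0, s0_sq = np.inf, float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300)))))
    if d0 == 0:
        s2_post = s2
        df_total = np.full_like(s2, df_res)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
        df_total = np.full_like(s2, d0 + df_res)
    tstat = B[:, coef] / np.sqrt(s2_post * v)
    with np.errstate(invalid="ignore"):
        pvals = np.where(
            np.isinf(df_total),
            2.0 * sps.norm.sf(np.abs(tstat)),
            2.0 * sps.t.sf(np.abs(tstat), df_total),
        )
    return pd.DataFrame(
        {
            "coef": B[:, coef],
            "se": np.sqrt(s2_post * v),
            "t": tstat,
            "p": pvals,
            "s2": s2,
            "s2_post": s2_post,
            "df_total": df_total,
            "d0": d0,
            "s0_sq": s0_sq,
        }
    )


def da_moderated_t(exp: MicrobiomeExperiment, config: DAConfig) -> pd.DataFrame:
    """logCPM + empirical-Bayes moderated-t differential abundance (limma-style)."""
    exp = _prepare(exp, config)
    X, names, levels, _ = _design_matrix(exp, config)
    logcpm = counts_to_logcpm(exp.counts)
    fit = moderated_t_fit(logcpm.to_numpy(dtype=float), X, coef=1)
    flags = np.ones(exp.n_features, dtype=bool)
    return _assemble_result(
        exp, config, exp.feature_ids,
        fit["coef"].to_numpy(),  # logCPM is base-2, so the coefficient IS log2fc
        fit["se"].to_numpy(),
        fit["t"].to_numpy(),
        fit["p"].to_numpy(),
        {"method": "moderated_t", "contrast": f"{levels[1]} vs {levels[0]}"},
        flags,
    )


def differential_abundance(exp: MicrobiomeExperiment, config: DAConfig) -> pd.DataFrame:
    """Dispatch to the configured differential-abundance path."""
    if config.method == "nb_wald":
        return da_nb_wald(exp, config)
    return da_moderated_t(exp, config)
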