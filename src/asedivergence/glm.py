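"""GLM testing machinery for allele-specific count data.

Two model families drive every downstream call in the pipeline:

* negative-binomial (NB) log-link GLMs with quasi-likelihood (QL) F-tests for
  differential (total or allelic) expression, with gene-wise dispersions
  estimated by Cox-Reid adjusted profile likelihood and shrunk toward a
  mean-dependent trend (empirical Bayes);
* quasi-binomial logit GLMs on paired (O, S) allele counts for ratio
  contrasts (the trans test F0-vs-F1 and the imprinting test F1A-vs-F1B),
  with the dispersion estimated from Pearson residuals and the group effect
  assessed by an F-test on the scaled deviance change.

Everything is vectorized across genes: a model fit is a handful of IRLS
sweeps over (genes x samples) arrays, so testing a few thousand genes takes
well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DispersionEstimates",
    "estimate_dispersions",
    "nb_glm_test",
    "qb_ratio_test",
    "bh_adjust",
    "joint_temperature_model",
]

_EPS = 1e-12
_PHI_FLOOR = 1e-8


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries are excluded from the ranking and propagate as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    pv = p[ok]
    n = pv.size
    if n:
        order = np.argsort(pv, kind="mergesort")
        scaled = pv[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        res = np.empty(n)
        res[order] = np.minimum(adj, 1.0)
        out[ok] = res
    return out


# --------------------------------------------------------------------------
# negative-binomial IRLS machinery
# --------------------------------------------------------------------------

def _nb_loglik(y, mu, phi):
    """NB log-likelihood summed over samples; phi broadcast (G, 1)."""
    inv = 1.0 / np.maximum(phi, _PHI_FLOOR)
    mu = np.maximum(mu, _EPS)
    ll = (special.gammaln(y + inv) - special.gammaln(inv)
          - special.gammaln(y + 1.0)
          + y * np.log(phi * mu / (1.0 + phi * mu))
          - inv * np.log1p(phi * mu))
    return ll.sum(axis=1)


def _nb_deviance(y, mu, phi):
    """NB residual deviance per gene (2 * (saturated ll - model ll))."""
    mu = np.maximum(mu, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.maximum(y, _EPS) / mu), 0.0)
        t2 = (y + 1.0 / phi) * (np.log1p(phi * y) - np.log1p(phi * mu))
    return 2.0 * (t1 - t2).sum(axis=1)


def _fit_nb_glm(y, X, offset, phi, max_iter=50, tol=1e-8):
    """Vectorized IRLS fit of an NB log-link GLM for every gene at once.

    Parameters
    ----------
    y : (G, n) counts
    X : (n, p) shared design matrix
    offset : (n,) or (G, n) log effective library sizes
    phi : (G,) dispersions

    Returns
    -------
    beta (G, p), mu (G, n), deviance (G,)
    """
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))[:, None]
    phi = np.maximum(phi, _PHI_FLOOR)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))

    eta = np.clip(np.log(np.maximum(y, 0.5)), -30.0, 30.0)
    beta, *_ = np.linalg.lstsq(X, (eta - offset).T, rcond=None)
    beta = beta.T  # (G, p)
    ridge = 1e-10 * np.eye(p)

    dev = np.full(G, np.inf)
    for _ in range(max_iter):
        eta = np.clip(offset + beta @ X.T, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / np.maximum(mu, _EPS)
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True) + ridge
        XtWz = np.einsum("ni,gn->gi", X, W * z, optimize=True)
        beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        new_dev = _nb_deviance(y, np.exp(np.clip(offset + beta @ X.T, -30, 30)),
                               phi)
        if np.all(np.abs(new_dev - dev) < tol * (np.abs(dev) + 1.0)):
            dev = new_dev
            break
        dev = new_dev
    eta = np.clip(offset + beta @ X.T, -30.0, 30.0)
    mu = np.exp(eta)
    return beta, mu, _nb_deviance(y, mu, phi)


def _cox_reid_adjustment(X, W):
    """0.5 * logdet(X'WX) per gene; W is (G, n)."""
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True)
    sign, logdet = np.linalg.slogdet(XtWX + 1e-10 * np.eye(X.shape[1]))
    return 0.5 * logdet


# --------------------------------------------------------------------------
# dispersion estimation
# --------------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    """Gene-wise, trended, and shrunk NB dispersions.

    ``shrunk`` is what the tests consume: the maximizer of the gene's
    Cox-Reid adjusted profile likelihood plus ``prior_df / residual_df``
    copies of the average profile likelihood of genes with similar abundance
    (weighted-likelihood empirical Bayes).
    """

    genewise: np.ndarray
    trended: np.ndarray
    shrunk: np.ndarray
    ave_log_cpm: np.ndarray
    prior_df: float

    def __post_init__(self):
        for arr in (self.genewise, self.trended, self.shrunk):
            if np.any(arr < 0):
                raise ValueError("dispersions must be non-negative")


def _interp_argmax(loggrid, apl):
    """Parabolic interpolation of the grid argmax, per gene."""
    G, K = apl.shape
    idx = np.argmax(apl, axis=1)
    lo = np.clip(idx, 1, K - 2)
    f0 = apl[np.arange(G), lo - 1]
    f1 = apl[np.arange(G), lo]
    f2 = apl[np.arange(G), lo + 1]
    denom = f0 - 2.0 * f1 + f2
    shift = np.where(np.abs(denom) > 1e-12,
                     0.5 * (f0 - f2) / np.where(denom == 0, 1, denom), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = loggrid[1] - loggrid[0]
    best = loggrid[lo] + shift * step
    # keep boundary maxima on the boundary
    best = np.where(idx == 0, loggrid[0], best)
    best = np.where(idx == K - 1, loggrid[-1], best)
    return np.exp(best)


def estimate_dispersions(counts, design, offset=None, prior_df=10.0,
                         grid=None, n_bins=20) -> DispersionEstimates:
    """Estimate per-gene NB dispersions by adjusted profile likelihood.

    Parameters
    ----------
    counts : (G, n) array or DataFrame of counts.
    design : (n, p) design matrix (e.g. one-hot group membership).
    offset : log effective library sizes; defaults to log column sums.
    prior_df : prior degrees of freedom for shrinkage toward the trend.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y.sum(axis=1) == 0):
        raise ValueError("all-zero genes must be filtered before "
                         "dispersion estimation")
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("need at least one residual degree of freedom")
    if offset is None:
        offset = np.log(y.sum(axis=0))
    offset = np.asarray(offset, dtype=float)
    if grid is None:
        grid = np.logspace(-8, 1.5, 25)
    loggrid = np.log(grid)

    G = y.shape[0]
    apl = np.empty((G, grid.size))
    for k, phi in enumerate(grid):
        phivec = np.full(G, phi)
        _, mu, _ = _fit_nb_glm(y, X, offset, phivec, max_iter=12)
        W = mu / (1.0 + phi * mu)
        apl[:, k] = _nb_loglik(y, mu, np.full((G, 1), phi)) \
            - _cox_reid_adjustment(X, W)

    lib = np.exp(offset)
    ave_log_cpm = np.log2(((y + 0.5) / lib * 1e6).mean(axis=1))

    genewise = _interp_argmax(loggrid, apl)

    # abundance bins -> average APL curve per bin
    order = np.argsort(ave_log_cpm)
    bins = np.array_split(order, min(n_bins, max(1, G // 10)))
    bin_apl = np.empty((len(bins), grid.size))
    bin_of_gene = np.empty(G, dtype=int)
    for b, members in enumerate(bins):
        bin_apl[b] = apl[members].mean(axis=0)
        bin_of_gene[members] = b
    trended_by_bin = _interp_argmax(loggrid, bin_apl)
    trended = trended_by_bin[bin_of_gene]

    prior_n = prior_df / max(n - p, 1)
    shrunk = _interp_argmax(loggrid, apl + prior_n * bin_apl[bin_of_gene])

    return DispersionEstimates(genewise=genewise, trended=trended,
                               shrunk=shrunk, ave_log_cpm=ave_log_cpm,
                               prior_df=float(prior_df))


# --------------------------------------------------------------------------
# quasi-likelihood moderation (limma-style variance squeezing)
# --------------------------------------------------------------------------

def _trigamma_inverse(x):
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def squeeze_var(s2, df):
    """Moment-match a scaled F prior to gene-wise variances (limma fitFDist).

    Returns (posterior s2, prior df, prior s2); prior df is ``inf`` when the
    gene-wise variances are less dispersed than chi-square sampling noise.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-10)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if s2.size < 2:  # nothing to pool across
        return s2, 0.0, float(s2.mean())
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = max(e.var(ddof=1) - special.polygamma(1, df / 2.0).mean(), 0.0)
    if evar > 0:
        df_prior = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s2_prior = float(np.exp(emean + special.digamma(df_prior / 2.0)
                                - np.log(df_prior / 2.0)))
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
    w = min(df_prior, 1e12)
    s2_post = (df * s2 + w * s2_prior) / (df + w)
    return s2_post, df_prior, s2_prior


def _ql_f_test(lr, df_diff, s2, df_resid):
    """Quasi-likelihood F-test with empirical-Bayes squeezed denominators."""
    s2_post, df_prior, _ = squeeze_var(s2, df_resid)
    fstat = (lr / df_diff) / np.maximum(s2_post, 1e-10)
    df2 = df_resid + min(df_prior, 1e12)
    pvals = stats.f.sf(np.maximum(fstat, 0.0), df_diff, df2)
    return fstat, pvals


# --------------------------------------------------------------------------
# NB GLM two-group test
# --------------------------------------------------------------------------

def _as_matrix(counts):
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), counts.index
    arr = np.asarray(counts, dtype=float)
    return arr, pd.RangeIndex(arr.shape[0])


def nb_glm_test(counts, groups, effective_lib_sizes, dispersion,
                family="nb_glm", levels=None) -> pd.DataFrame:
    """Two-group NB GLM differential test with a quasi-likelihood F-test.

    Parameters
    ----------
    counts : (G, n) counts (DataFrame rows = genes).
    groups : length-n labels with exactly two levels; the effect is
        log2(level2 / level1) with levels in order of first appearance
        unless ``levels`` fixes the (baseline, contrast) order explicitly.
    effective_lib_sizes : length-n positive reals (library size x TMM factor).
    dispersion : per-gene NB dispersions (typically ``shrunk``).

    Returns
    -------
    DataFrame with columns gene, effect (log2 fold-change), p, fdr, family.
    """
    y, genes = _as_matrix(counts)
    groups = np.asarray(groups)
    if levels is None:
        levels = list(dict.fromkeys(groups))
    if len(levels) != 2 or set(levels) != set(np.unique(groups)):
        raise ValueError("exactly two groups required")
    g2 = (groups == levels[1]).astype(float)
    n = y.shape[1]
    if min((groups == lv).sum() for lv in levels) < 2:
        raise ValueError("each group needs >= 2 replicates")
    offset = np.log(np.asarray(effective_lib_sizes, dtype=float))

    X_full = np.column_stack([np.ones(n), g2])
    X_null = np.ones((n, 1))
    phi = np.asarray(dispersion, dtype=float)

    beta_full, _, dev_full = _fit_nb_glm(y, X_full, offset, phi)
    _, _, dev_null = _fit_nb_glm(y, X_null, offset, phi)
    lr = np.maximum(dev_null - dev_full, 0.0)

    df_resid = n - 2
    s2 = dev_full / df_resid
    _, pvals = _ql_f_test(lr, 1, s2, df_resid)

    # identical counts in both groups give lr == 0 -> p == 1 exactly
    pvals = np.where(lr <= 1e-12, 1.0, pvals)

    effect = beta_full[:, 1] / np.log(2.0)
    zero_grp = ((y[:, g2 == 0].sum(axis=1) == 0)
                | (y[:, g2 == 1].sum(axis=1) == 0))
    effect = np.clip(effect, -43.0, 43.0)  # eta clip bound on log2 scale

    res = pd.DataFrame({
        "gene": genes,
        "effect": effect,
        "p": pvals,
        "fdr": bh_adjust(pvals),
        "family": family,
        "zero_group": zero_grp,
    }).set_index("gene")
    return res


# --------------------------------------------------------------------------
# quasi-binomial ratio test
# --------------------------------------------------------------------------

def _binom_deviance(o, n, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(o > 0, o * np.log(np.maximum(o, _EPS) / (n * p)), 0.0)
        s = n - o
        t2 = np.where(s > 0,
                      s * np.log(np.maximum(s, _EPS) / (n * (1.0 - p))), 0.0)
    return 2.0 * (t1 + t2)


def qb_ratio_test(o_counts, s_counts, groups, family="qb_ratio",
                  min_trials=1.0) -> pd.DataFrame:
    """Quasi-binomial test for a difference in O/(O+S) between two groups.

    Each library contributes one (O successes, O+S trials) observation.  The
    group model has closed-form fitted proportions (pooled within group); the
    dispersion is the Pearson statistic of the full model over its residual
    degrees of freedom, and the group effect is an F-test on the scaled
    deviance change.  Libraries with O+S = 0 are dropped for that gene.

    Counts may be non-integral (e.g. depth-normalized), as quasi-likelihood
    requires only means and variances.

    Returns a DataFrame with the effect reported as the difference in
    logit(O fraction) between groups (group2 - group1) and as
    ``delta_log2_ratio`` (identical up to the log base).
    """
    o, genes = _as_matrix(o_counts)
    s, _ = _as_matrix(s_counts)
    if o.shape != s.shape:
        raise ValueError("O and S count matrices must be congruent")
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    in2 = groups == levels[1]

    ntr = o + s
    use = ntr >= min_trials  # (G, L) libraries contributing per gene

    def pooled(mask_cols):
        m = use & mask_cols
        osum = np.where(m, o, 0.0).sum(axis=1)
        nsum = np.where(m, ntr, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nsum > 0, osum / nsum, np.nan)
        return np.clip(p, 1e-10, 1 - 1e-10), nsum

    p1, n1 = pooled(np.broadcast_to(~in2, o.shape))
    p2, n2 = pooled(np.broadcast_to(in2, o.shape))
    p0, _ = pooled(np.ones_like(use, dtype=bool))

    # full-model fitted proportion per library
    pfit = np.where(np.broadcast_to(in2, o.shape), p2[:, None], p1[:, None])

    dev_full = np.where(use, _binom_deviance(o, ntr, pfit), 0.0).sum(axis=1)
    dev_null = np.where(use, _binom_deviance(o, ntr, p0[:, None]), 0.0).sum(axis=1)
    lr = np.maximum(dev_null - dev_full, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.where(use,
                           (o - ntr * pfit) ** 2
                           / np.maximum(ntr * pfit * (1 - pfit), _EPS), 0.0)
    nlib = use.sum(axis=1)
    df_resid = nlib - 2
    disp = np.where(df_resid > 0, pearson.sum(axis=1) / np.maximum(df_resid, 1),
                    np.nan)
    disp = np.maximum(disp, 1e-8)

    # share dispersion information across genes (empirical-Bayes squeezing);
    # the gained prior df enter the F denominator
    testable = df_resid > 0
    disp_post = disp.copy()
    df_total = np.maximum(df_resid, 1).astype(float)
    if testable.sum() >= 10:
        post, df_prior, _ = squeeze_var(disp[testable],
                                        df_resid[testable].astype(float))
        disp_post[testable] = post
        df_total = df_resid + min(df_prior, 1e12)

    with np.errstate(invalid="ignore", divide="ignore"):
        fstat = lr / disp_post
        pvals = np.where(testable, stats.f.sf(fstat, 1, np.maximum(df_total, 1)),
                         np.nan)
    pvals = np.where(lr <= 1e-12, 1.0, pvals)
    pvals = np.where(testable, pvals, np.nan)

    effect = special.logit(p2) - special.logit(p1)

    res = pd.DataFrame({
        "gene": genes,
        "effect": effect,
        "delta_log2_ratio": effect / np.log(2.0),
        "p": pvals,
        "fdr": bh_adjust(pvals),
        "family": family,
        "n_libraries": nlib,
    }).set_index("gene")
    return res


# --------------------------------------------------------------------------
# binomial IRLS for the joint model
# --------------------------------------------------------------------------

def _fit_binom_glm(o, ntr, X, use, max_iter=50, tol=1e-10):
    """Vectorized binomial logit IRLS; ``use`` masks libraries per gene."""
    G, L = o.shape
    p = X.shape[1]
    frac = np.where(use, o / np.maximum(ntr, _EPS), 0.5)
    eta = special.logit(np.clip(frac, 1e-4, 1 - 1e-4))
    w0 = np.where(use, 1.0, 0.0)
    XtWX = np.einsum("ni,gn,nj->gij", X, w0, X, optimize=True) + 1e-10 * np.eye(p)
    XtWz = np.einsum("ni,gn->gi", X, w0 * eta, optimize=True)
    beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
    dev = np.full(G, np.inf)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T, -30.0, 30.0)
        mu = special.expit(eta)
        W = np.where(use, ntr * mu * (1.0 - mu), 0.0)
        z = eta + np.where(use, (o - ntr * mu)
                           / np.maximum(ntr * mu * (1 - mu), _EPS), 0.0)
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True) \
            + 1e-8 * np.eye(p)
        XtWz = np.einsum("ni,gn->gi", X, W * z, optimize=True)
        beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        mu = special.expit(np.clip(beta @ X.T, -30, 30))
        new_dev = np.where(use, _binom_deviance(o, ntr, np.clip(mu, 1e-10, 1 - 1e-10)),
                           0.0).sum(axis=1)
        if np.all(np.abs(new_dev - dev) < tol * (np.abs(dev) + 1.0)):
            dev = new_dev
            break
        dev = new_dev
    mu = special.expit(np.clip(beta @ X.T, -30, 30))
    return beta, mu, dev


def _design_two_factor(f1, f2):
    """Full-interaction and nested designs for two categorical factors."""
    f1 = np.asarray(f1)
    f2 = np.asarray(f2)
    l1 = list(dict.fromkeys(f1))
    l2 = list(dict.fromkeys(f2))
    n = f1.size
    cols_main1 = [(f1 == lv).astype(float) for lv in l1[1:]]
    cols_main2 = [(f2 == lv).astype(float) for lv in l2[1:]]
    cols_int = [((f1 == a) & (f2 == b)).astype(float)
                for a in l1[1:] for b in l2[1:]]
    one = [np.ones(n)]
    X_full = np.column_stack(one + cols_main1 + cols_main2 + cols_int)
    X_add = np.column_stack(one + cols_main1 + cols_main2)
    X_f2only = np.column_stack(one + cols_main2)
    X_f1only = np.column_stack(one + cols_main1)
    return X_full, X_add, X_f1only, X_f2only


def _nb_term_tests(y, offset, phi, factor_main, factor_temp, genes, prefix):
    X_full, X_add, X_main_only, X_temp_only = _design_two_factor(
        factor_main, factor_temp)
    n = y.shape[1]
    fits = {}
    for name, X in (("full", X_full), ("add", X_add),
                    ("main_only", X_main_only), ("temp_only", X_temp_only)):
        fits[name] = (_fit_nb_glm(y, X, offset, phi), X.shape[1])
    (_, _, dev_full), p_full = fits["full"]
    df_resid = n - p_full
    s2 = dev_full / df_resid
    out = {}
    for term, (reduced, base) in {
        "interaction": ("add", "full"),
        "main": ("temp_only", "add"),
        "temperature": ("main_only", "add"),
    }.items():
        (_, _, dev_r), p_r = fits[reduced]
        (_, _, dev_b), p_b = fits[base]
        lr = np.maximum(dev_r - dev_b, 0.0)
        df_diff = p_b - p_r
        _, pv = _ql_f_test(lr, df_diff, s2, df_resid)
        pv = np.where(lr <= 1e-12, 1.0, pv)
        out[f"{prefix}_{term}"] = pd.DataFrame({
            "gene": genes, "effect": lr, "p": pv, "fdr": bh_adjust(pv),
            "family": f"{prefix}_{term}",
        }).set_index("gene")
    return out


def _qb_term_tests(o, ntr, use, factor_main, factor_temp, genes, prefix):
    X_full, X_add, X_main_only, X_temp_only = _design_two_factor(
        factor_main, factor_temp)
    fits = {}
    for name, X in (("full", X_full), ("add", X_add),
                    ("main_only", X_main_only), ("temp_only", X_temp_only)):
        fits[name] = (_fit_binom_glm(o, ntr, X, use), X.shape[1])
    (beta_f, mu_f, dev_full), p_full = fits["full"]
    nlib = use.sum(axis=1)
    df_resid = np.maximum(nlib - p_full, 1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.where(use, (o - ntr * mu_f) ** 2
                           / np.maximum(ntr * mu_f * (1 - mu_f), _EPS), 0.0)
    disp = np.maximum(pearson.sum(axis=1) / df_resid, 1e-8)
    if disp.size >= 10:
        disp, df_prior, _ = squeeze_var(disp, df_resid)
        df_resid = df_resid + min(df_prior, 1e12)
    out = {}
    for term, (reduced, base) in {
        "interaction": ("add", "full"),
        "main": ("temp_only", "add"),
        "temperature": ("main_only", "add"),
    }.items():
        (_, _, dev_r), p_r = fits[reduced]
        (_, _, dev_b), p_b = fits[base]
        lr = np.maximum(dev_r - dev_b, 0.0)
        df_diff = p_b - p_r
        fstat = lr / df_diff / disp
        pv = stats.f.sf(fstat, df_diff, df_resid)
        pv = np.where(lr <= 1e-12, 1.0, pv)
        out[f"{prefix}_{term}"] = pd.DataFrame({
            "gene": genes, "effect": lr, "p": pv, "fdr": bh_adjust(pv),
            "family": f"{prefix}_{term}",
        }).set_index("gene")
    return out


def joint_temperature_model(table, norm_factors=None, prior_df=10.0) -> dict:
    """Joint allele x temperature models across all environments.

    Fits, for every gene, (a) an NB GLM on F1 allelic counts with allele,
    temperature and allele x temperature terms, and (b) a quasi-binomial GLM
    on the O/(O+S) ratio with generation (F0 vs F1), temperature and their
    interaction.  Each term is tested by comparing nested models with an
    F-test; BH adjustment is applied within each term family.

    Returns a dict of TestResult frames keyed by
    ``allelic_{main,temperature,interaction}`` and
    ``ratio_{main,temperature,interaction}``.
    """
    from .preprocess import tmm_factors  # local import to avoid a cycle

    temps = table.temperatures
    if len(temps) < 2:
        raise ValueError("joint model requires at least two temperatures")

    # ---- NB allelic model on F1 allele channels
    f1 = table.subset_samples(table.samples["genotype"].isin(["F1A", "F1B"]))
    y = f1.counts.to_numpy(dtype=float)
    keep = y.sum(axis=1) > 0
    y = y[keep]
    genes = f1.counts.index[keep]
    if norm_factors is None:
        nf = tmm_factors(f1.counts.loc[genes]).factors.to_numpy()
    else:
        nf = np.asarray(norm_factors, dtype=float)
    eff = f1.lib_sizes().to_numpy() * nf
    offset = np.log(eff)
    allele = f1.samples["allele"].to_numpy()
    temp = f1.samples["temperature"].to_numpy()
    X_groups = np.column_stack([
        ((allele == a) & (temp == t)).astype(float)
        for a in ("O", "S") for t in temps])
    disp = estimate_dispersions(y, X_groups, offset=offset,
                                prior_df=prior_df)
    out = _nb_term_tests(y, offset, disp.trended, allele, temp, genes,
                         "allelic")

    # ---- quasi-binomial ratio model: generation x temperature
    o_mat, s_mat, gen, rtemp = _ratio_layout(table)
    okeep = o_mat[keep]
    skeep = s_mat[keep]
    ntr = okeep + skeep
    use = ntr > 0
    out.update(_qb_term_tests(okeep, ntr, use, gen, rtemp, genes, "ratio"))
    return out


def _ratio_layout(table):
    """Per-library (O, S) pairs for the ratio model, all temperatures.

    F0 contributes one pair per replicate (the O-strain and S-strain
    libraries of the same replicate index, depth-normalized to a common
    scale); each F1 library contributes its two allele channels.
    """
    sm = table.samples
    counts = table.counts
    eff = table.lib_sizes()
    gm = float(np.exp(np.log(eff).mean()))
    scaled = counts.to_numpy(dtype=float) / eff.to_numpy() * gm

    o_cols, s_cols, gen, temps = [], [], [], []
    idx = {sid: i for i, sid in enumerate(counts.columns)}
    for t in table.temperatures:
        at = sm[sm["temperature"] == t]
        f0o = at[at["channel"] == "F0_O"].sort_values("replicate")
        f0s = at[at["channel"] == "F0_S"].sort_values("replicate")
        for (sid_o, _), (sid_s, _) in zip(f0o.iterrows(), f0s.iterrows()):
            o_cols.append(scaled[:, idx[sid_o]])
            s_cols.append(scaled[:, idx[sid_s]])
            gen.append("F0")
            temps.append(t)
        for gt in ("F1A", "F1B"):
            go = at[at["channel"] == f"{gt}_O"].sort_values("replicate")
            gs = at[at["channel"] == f"{gt}_S"].sort_values("replicate")
            for (sid_o, _), (sid_s, _) in zip(go.iterrows(), gs.iterrows()):
                o_cols.append(scaled[:, idx[sid_o]])
                s_cols.append(scaled[:, idx[sid_s]])
                gen.append("F1")
                temps.append(t)
    return (np.column_stack(o_cols), np.column_stack(s_cols),
            np.asarray(gen), np.asarray(temps))
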