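"""Normalization, expression filtering, and rank-matched down-sampling.

TMM (trimmed mean of M-values) corrects between-library comparisons for RNA
composition: for each library versus a reference, gene-wise log-ratios of
library-size-scaled proportions (M) are doubly trimmed — by the M values
themselves and by absolute abundance (A) — and averaged with inverse
delta-method variances as weights.  The implementation follows the standard
edgeR semantics (reference selection by upper quartile, 30 % / 5 % trims,
geometric centering of the factors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AlleleCountTable

__all__ = ["NormalizationFactors", "tmm_factors", "filter_expressed",
           "downsample_rank_matched"]


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors, geometrically centered to product 1."""

    factors: pd.Series
    reference: str

    def __post_init__(self):
        if np.any(self.factors.to_numpy() <= 0):
            raise ValueError("normalization factors must be positive")

    def effective_lib_sizes(self, lib_sizes: pd.Series) -> pd.Series:
        return lib_sizes * self.factors


def _counts_frame(table) -> pd.DataFrame:
    if isinstance(table, AlleleCountTable):
        return table.counts
    return pd.DataFrame(table)


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a):
    """One library vs reference: doubly trimmed weighted mean of M."""
    pos = (obs > 0) & (ref > 0)
    obs = obs[pos].astype(float)
    ref = ref[pos].astype(float)
    if obs.size == 0:
        return 1.0
    p_o = obs / n_obs
    p_r = ref / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # delta-method (asymptotic binomial) variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not np.any(keep):
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(table, trim_M: float = 0.30, trim_A: float = 0.05,
                lib_sizes=None, reference=None) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    Parameters
    ----------
    table : AlleleCountTable or genes x samples DataFrame.
    trim_M, trim_A : two-sided trim fractions on the log-ratio and on the
        average-abundance axes.
    reference : sample id; default is the library whose upper-quartile
        count rate is closest to the mean upper quartile.
    """
    counts = _counts_frame(table)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if lib_sizes is None:
        if isinstance(table, AlleleCountTable):
            lib_sizes = table.lib_sizes()
        else:
            lib_sizes = counts.sum(axis=0).astype(float)
    lib = np.asarray(lib_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")
    y = counts.to_numpy(dtype=float)

    if reference is None:
        uq = np.array([np.quantile(y[:, j], 0.75) / lib[j]
                       for j in range(y.shape[1])])
        reference = counts.columns[int(np.argmin(np.abs(uq - uq.mean())))]
    r = counts.columns.get_loc(reference)

    raw = np.array([
        1.0 if j == r else _tmm_pair(y[:, j], y[:, r], lib[j], lib[r],
                                     trim_M, trim_A)
        for j in range(y.shape[1])])
    centered = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(
        factors=pd.Series(centered, index=counts.columns, name="tmm"),
        reference=str(reference))


def filter_expressed(f0_table: AlleleCountTable, f1_table: AlleleCountTable,
                     min_top: int = 20) -> pd.Series:
    """Expression mask: detected everywhere, well-covered somewhere.

    A gene passes in the parents if every F0 library has at least one read
    and at least one library has >= ``min_top``.  In the F1, the two allele
    channels of each library are summed first and the same rule applied.
    The returned boolean Series is the AND of the two rules.
    """
    f0 = _counts_frame(f0_table)
    f1tot = _counts_frame(f1_table.f1_totals()
                          if isinstance(f1_table, AlleleCountTable)
                          else f1_table)
    if isinstance(f1_table, AlleleCountTable):
        f1tot = f1tot[[c for c in f1tot.columns
                       if not str(c).startswith("F0")]]

    def rule(df):
        arr = df.to_numpy()
        return (arr >= 1).all(axis=1) & (arr >= min_top).any(axis=1)

    mask = rule(f0) & rule(f1tot)
    return pd.Series(mask, index=f0.index, name="expressed")


def downsample_rank_matched(table: AlleleCountTable, seed: int,
                            ) -> AlleleCountTable:
    """Equalize sequencing depth across genotypes by rank-matched sampling.

    Within each temperature, the replicate libraries of every genotype are
    ranked by total read count; for each rank the target is the smallest
    total at that rank across genotypes, and every library is reduced to its
    target by sampling reads without replacement (multivariate
    hypergeometric on the gene x allele count vector).  This maximizes the
    number of reads retained while equalizing depth at every rank.

    The two allele channels of an F1 library are down-sampled jointly, so a
    library's allelic ratio is disturbed only by the sampling itself.
    """
    rng = np.random.default_rng(seed)
    sm = table.samples
    new_counts = table.counts.copy()

    for temp in table.temperatures:
        at = sm[sm["temperature"] == temp]
        # physical libraries: (genotype, replicate) -> sample columns
        libs = {}
        for (gt, rep), grp in at.groupby(["genotype", "replicate"],
                                         sort=False):
            libs[(gt, rep)] = list(grp.index)
        totals = {k: int(table.counts[cols].to_numpy().sum())
                  for k, cols in libs.items()}
        by_gt: dict[str, list] = {}
        for (gt, rep), tot in totals.items():
            by_gt.setdefault(gt, []).append(((gt, rep), tot))
        for gt in by_gt:
            by_gt[gt].sort(key=lambda kv: kv[1])
        n_ranks = min(len(v) for v in by_gt.values())
        for rank in range(n_ranks):
            target = min(by_gt[gt][rank][1] for gt in by_gt)
            if target == 0:
                raise ValueError(f"rank {rank} at {temp} has an empty library")
            for gt in by_gt:
                key, tot = by_gt[gt][rank]
                cols = libs[key]
                vec = table.counts[cols].to_numpy().ravel(order="F")
                if tot == target:
                    continue
                sampled = rng.multivariate_hypergeometric(
                    vec.astype(np.int64), target, method="marginals")
                new = sampled.reshape((len(table.genes), len(cols)),
                                      order="F")
                for i, c in enumerate(cols):
                    new_counts[c] = new[:, i]

    meta = table.samples.copy()
    meta["lib_size"] = new_counts.to_numpy().sum(axis=0)
    return AlleleCountTable(new_counts, meta)
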