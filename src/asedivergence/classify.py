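"""Regulatory-category and mode-of-inheritance classification.

Three test families feed the cis/trans call for each gene at each
temperature:

* **F0** — NB GLM differential expression between the parental strains;
* **F1** — NB GLM differential *allelic* expression within the hybrids
  (the cis signal: both alleles share one trans environment);
* **T** — quasi-binomial contrast of the O/(O+S) ratio between parents and
  hybrids (the trans signal: any parental ratio not preserved in the F1).

The seven-way rule table combines the three BH-adjusted significance flags;
effect sizes are e_cis = log2(F1_O / F1_S) and
e_trans = log2(F0_O / F0_S) - e_cis, so e_cis + e_trans reconstructs the
parental log ratio by definition.  Mode of inheritance compares F1 total
expression against each parent (NB GLM + 1.25-fold gate), and
"dominance-swapped" genes are those dominant for opposite parents at the
two extreme temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .preprocess import filter_expressed, tmm_factors
from .tables import AlleleCountTable

__all__ = [
    "imprinting_screen", "effect_sizes", "classify_cis_trans",
    "classify_inheritance", "dominance_swapped", "run_pipeline",
    "PipelineResult", "CATEGORIES", "MODES",
]

CATEGORIES = ("not_different", "cis_only", "trans_only", "cis_plus_trans",
              "cis_x_trans", "compensatory", "ambiguous")
MODES = ("not_different", "O_dominant", "S_dominant", "additive",
         "over_dominant", "under_dominant")


# --------------------------------------------------------------------------
# imprinting screen
# --------------------------------------------------------------------------

@dataclass
class ImprintingResult:
    flagged: list
    results: dict  # temperature -> TestResult frame


def imprinting_screen(table: AlleleCountTable, alpha: float = 0.05,
                      ) -> ImprintingResult:
    """Parent-of-origin screen: F1A vs F1B allelic ratio per temperature.

    The allelic ratio of a library is internal to that library, so raw
    counts enter the quasi-binomial test directly.  A gene is flagged when
    its BH-adjusted p is <= ``alpha`` at any temperature; flagged genes are
    excluded before the reciprocal crosses are pooled.
    """
    flagged: set = set()
    results = {}
    for temp in table.temperatures:
        at = table.at_temperature(temp)
        o_cols, s_cols, groups = [], [], []
        for gt in ("F1A", "F1B"):
            ot = at.channel(f"{gt}_O")
            st = at.channel(f"{gt}_S")
            for (sid_o, _), (sid_s, _) in zip(ot.samples.iterrows(),
                                              st.samples.iterrows()):
                o_cols.append(at.counts[sid_o])
                s_cols.append(at.counts[sid_s])
                groups.append(gt)
        res = glm.qb_ratio_test(pd.concat(o_cols, axis=1),
                                pd.concat(s_cols, axis=1),
                                groups, family=f"imprinting_{temp}")
        results[temp] = res
        flagged |= set(res.index[res["fdr"] <= alpha])
    return ImprintingResult(flagged=sorted(flagged), results=results)


# --------------------------------------------------------------------------
# effect sizes
# --------------------------------------------------------------------------

def effect_sizes(f0_o_mean, f0_s_mean, f1_o_mean, f1_s_mean,
                 pseudo: float = 0.5):
    """cis and trans effect sizes from normalized channel means.

    e_cis is the log2 allelic ratio inside the F1 (shared trans
    environment); e_trans is whatever part of the parental log2 ratio the
    cis component does not explain.  A ``pseudo`` count protects zeros in
    reported effects only — tests never see it.
    """
    def safe(x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, x, pseudo)

    e_cis = np.log2(safe(f1_o_mean) / safe(f1_s_mean))
    f0_ratio = np.log2(safe(f0_o_mean) / safe(f0_s_mean))
    return e_cis, f0_ratio - e_cis


def effect_correlations(regulatory: pd.DataFrame, which: str = "e_cis",
                        ) -> pd.DataFrame:
    """Spearman correlation of per-gene effects between temperatures."""
    wide = regulatory.pivot_table(index="gene", columns="temperature",
                                  values=which, sort=False)
    return wide.corr(method="spearman")


# --------------------------------------------------------------------------
# rule tables
# --------------------------------------------------------------------------

def classify_cis_trans(res_f0: pd.DataFrame, res_f1: pd.DataFrame,
                       res_t: pd.DataFrame, e_cis, e_trans,
                       alpha: float = 0.05) -> pd.Series:
    """Seven-way cis/trans category from the three test families.

    Rule table on the BH flags (F0, F1, T):

    ========= ========= ====== =====================================
    F0        F1        T      category
    ========= ========= ====== =====================================
    sig       sig       ns     cis_only
    sig       ns        sig    trans_only
    sig       sig       sig    cis_plus_trans (same-sign effects)
    sig       sig       sig    cis_x_trans (opposite-sign effects)
    ns        sig       sig    compensatory
    ns        ns        ns     not_different
    exactly one significant    ambiguous
    ========= ========= ====== =====================================
    """
    for res in (res_f1, res_t):
        if not res.index.equals(res_f0.index):
            raise ValueError("test results must cover the same genes")
    s0 = (res_f0["fdr"] <= alpha).to_numpy()
    s1 = (res_f1["fdr"] <= alpha).to_numpy()
    st = (res_t["fdr"] <= alpha).to_numpy()
    e_cis = np.asarray(e_cis, dtype=float)
    e_trans = np.asarray(e_trans, dtype=float)

    same_sign = np.sign(e_cis) == np.sign(e_trans)
    cat = np.full(s0.shape, "ambiguous", dtype=object)
    cat[~s0 & ~s1 & ~st] = "not_different"
    cat[s0 & s1 & ~st] = "cis_only"
    cat[s0 & ~s1 & st] = "trans_only"
    cat[s0 & s1 & st & same_sign] = "cis_plus_trans"
    cat[s0 & s1 & st & ~same_sign] = "cis_x_trans"
    cat[~s0 & s1 & st] = "compensatory"
    return pd.Series(cat, index=res_f0.index, name="category")


def classify_inheritance(res_vs_o: pd.DataFrame, res_vs_s: pd.DataFrame,
                         fold_threshold: float = 1.25,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Six-way mode of inheritance from the two parent-offspring tests.

    ``res_vs_o``/``res_vs_s`` are NB GLM results on total expression with
    effect = log2(F1 / parent).  A parent comparison is "diverged" when its
    BH-adjusted p is <= ``alpha`` AND the normalized fold-change exceeds
    ``fold_threshold``; dominance requires the resembled parent to be
    non-diverged.  When both comparisons diverge, the F1 lies strictly
    between the parents (additive), above both (over-dominant) or below
    both (under-dominant).
    """
    if not res_vs_o.index.equals(res_vs_s.index):
        raise ValueError("test results must cover the same genes")
    log_fold = np.log2(fold_threshold)
    eo = res_vs_o["effect"].to_numpy()
    es = res_vs_s["effect"].to_numpy()
    div_o = (res_vs_o["fdr"] <= alpha).to_numpy() & (np.abs(eo) > log_fold)
    div_s = (res_vs_s["fdr"] <= alpha).to_numpy() & (np.abs(es) > log_fold)

    mode = np.full(eo.shape, "not_different", dtype=object)
    mode[div_s & ~div_o] = "O_dominant"
    mode[div_o & ~div_s] = "S_dominant"
    both = div_o & div_s
    mode[both & (np.sign(eo) != np.sign(es))] = "additive"
    mode[both & (eo > 0) & (es > 0)] = "over_dominant"
    mode[both & (eo < 0) & (es < 0)] = "under_dominant"
    return pd.DataFrame({
        "mode": mode,
        "log2fc_vs_O": eo,
        "log2fc_vs_S": es,
        "diverged_from_O": div_o,
        "diverged_from_S": div_s,
    }, index=res_vs_o.index)


def dominance_swapped(calls_low: pd.DataFrame, calls_high: pd.DataFrame,
                      ) -> list:
    """Genes dominant for opposite parents at the two extreme temperatures."""
    lo = calls_low["mode"]
    hi = calls_high["mode"].reindex(lo.index)
    swap = ((lo == "O_dominant") & (hi == "S_dominant")) | \
           ((lo == "S_dominant") & (hi == "O_dominant"))
    return sorted(lo.index[swap])


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything the per-temperature analysis produces.

    ``regulatory`` and ``inheritance`` are long frames (one row per gene and
    temperature); ``summary`` mirrors the usual category-by-temperature
    count layout.
    """

    regulatory: pd.DataFrame
    inheritance: pd.DataFrame
    swapped: list
    imprinted: list
    expressed_mask: pd.Series
    tests: dict = field(default_factory=dict)
    joint: dict | None = None

    @property
    def summary(self) -> pd.DataFrame:
        reg = self.regulatory.pivot_table(index="category",
                                          columns="temperature",
                                          values="gene", aggfunc="count",
                                          fill_value=0, sort=False)
        inh = self.inheritance.pivot_table(index="mode",
                                           columns="temperature",
                                           values="gene", aggfunc="count",
                                           fill_value=0, sort=False)
        reg.index = pd.MultiIndex.from_product([["regulatory"], reg.index])
        inh.index = pd.MultiIndex.from_product([["inheritance"], inh.index])
        return pd.concat([reg, inh])


def _scaled_ratio_pairs(at: AlleleCountTable, genes, nf):
    """Depth-normalized (O, S) pairs for the trans test at one temperature."""
    eff = at.lib_sizes() * nf.factors
    gm = float(np.exp(np.log(eff).mean()))
    scaled = at.counts.loc[genes].div(eff, axis=1) * gm
    o_cols, s_cols, groups = [], [], []
    f0o = at.channel("F0_O").samples.sort_values("replicate")
    f0s = at.channel("F0_S").samples.sort_values("replicate")
    for (sid_o, _), (sid_s, _) in zip(f0o.iterrows(), f0s.iterrows()):
        o_cols.append(scaled[sid_o])
        s_cols.append(scaled[sid_s])
        groups.append("F0")
    for gt in ("F1A", "F1B"):
        go = at.channel(f"{gt}_O").samples.sort_values("replicate")
        gs = at.channel(f"{gt}_S").samples.sort_values("replicate")
        for (sid_o, _), (sid_s, _) in zip(go.iterrows(), gs.iterrows()):
            o_cols.append(scaled[sid_o])
            s_cols.append(scaled[sid_s])
            groups.append("F1")
    return (pd.concat(o_cols, axis=1), pd.concat(s_cols, axis=1), groups)


def run_pipeline(table: AlleleCountTable, alpha: float = 0.05,
                 fold_threshold: float = 1.25, prior_df: float = 10.0,
                 run_joint: bool = False, min_top: int = 20,
                 ) -> PipelineResult:
    """Full per-temperature cis/trans and inheritance analysis.

    Applies the expression filter, screens and removes putatively imprinted
    genes, then per temperature: TMM-normalizes each test's libraries, runs
    the F0 / F1 / T tests, classifies the seven regulatory categories,
    classifies the six inheritance modes from F1-vs-parent total-expression
    tests, and finally reports dominance-swapped genes across the two
    extreme temperatures.
    """
    f0 = table.subset_samples(table.samples["genotype"].str.startswith("F0"))
    f1 = table.subset_samples(~table.samples["genotype"].str.startswith("F0"))
    mask = filter_expressed(f0, f1, min_top=min_top)

    imp = imprinting_screen(
        table.subset_genes(mask.index[mask]), alpha=alpha)
    keep = [g for g in mask.index[mask] if g not in set(imp.flagged)]
    data = table.subset_genes(keep)

    tests: dict = {}
    reg_rows = []
    inh_rows = []
    inh_calls = {}
    for temp in data.temperatures:
        at = data.at_temperature(temp)

        # ---- F0 differential expression
        f0t = at.subset_samples(at.samples["genotype"].str.startswith("F0"))
        nf0 = tmm_factors(f0t)
        disp0 = glm.estimate_dispersions(
            f0t.counts, _group_design(f0t.samples["channel"]),
            offset=np.log(f0t.lib_sizes().to_numpy()
                          * nf0.factors.to_numpy()),
            prior_df=prior_df)
        res_f0 = glm.nb_glm_test(
            f0t.counts, f0t.samples["channel"].to_numpy(),
            f0t.lib_sizes().to_numpy() * nf0.factors.to_numpy(),
            disp0.trended, family=f"F0_{temp}", levels=["F0_S", "F0_O"])

        # ---- F1 allelic differential expression (cis evidence)
        f1t = at.subset_samples(~at.samples["genotype"].str.startswith("F0"))
        nf1 = tmm_factors(f1t)
        disp1 = glm.estimate_dispersions(
            f1t.counts, _group_design(f1t.samples["allele"]),
            offset=np.log(f1t.lib_sizes().to_numpy()
                          * nf1.factors.to_numpy()),
            prior_df=prior_df)
        res_f1 = glm.nb_glm_test(
            f1t.counts, f1t.samples["allele"].to_numpy(),
            f1t.lib_sizes().to_numpy() * nf1.factors.to_numpy(),
            disp1.trended, family=f"F1_{temp}", levels=["S", "O"])

        # ---- trans test: allelic ratio F0 vs F1
        nft = tmm_factors(at)
        o_mat, s_mat, groups = _scaled_ratio_pairs(at, data.genes, nft)
        res_t = glm.qb_ratio_test(o_mat, s_mat, groups, family=f"T_{temp}")

        tests[(temp, "F0")] = res_f0
        tests[(temp, "F1")] = res_f1
        tests[(temp, "T")] = res_t

        # ---- effects and category
        effq = at.lib_sizes() * nft.factors
        norm = at.counts.loc[data.genes].div(effq, axis=1)
        ch = at.samples["channel"]
        mean_of = {
            "F0_O": norm[ch.index[ch == "F0_O"]].mean(axis=1),
            "F0_S": norm[ch.index[ch == "F0_S"]].mean(axis=1),
            "F1_O": norm[ch.index[ch.isin(["F1A_O", "F1B_O"])]].mean(axis=1),
            "F1_S": norm[ch.index[ch.isin(["F1A_S", "F1B_S"])]].mean(axis=1),
        }
        scale = at.lib_sizes().mean()
        e_cis, e_trans = effect_sizes(
            mean_of["F0_O"] * scale, mean_of["F0_S"] * scale,
            mean_of["F1_O"] * scale, mean_of["F1_S"] * scale)
        category = classify_cis_trans(res_f0, res_f1, res_t,
                                      e_cis, e_trans, alpha=alpha)
        reg_rows.append(pd.DataFrame({
            "gene": res_f0.index, "temperature": temp,
            "category": category.to_numpy(),
            "e_cis": np.asarray(e_cis), "e_trans": np.asarray(e_trans),
            "p_F0": res_f0["p"].to_numpy(), "fdr_F0": res_f0["fdr"].to_numpy(),
            "p_F1": res_f1["p"].to_numpy(), "fdr_F1": res_f1["fdr"].to_numpy(),
            "p_T": res_t["p"].to_numpy(), "fdr_T": res_t["fdr"].to_numpy(),
        }))

        # ---- mode of inheritance on totals
        tot = at.f1_totals()
        res_o, res_s = {}, {}
        for parent in ("F0_O", "F0_S"):
            sub = tot.subset_samples(
                (tot.samples["channel"] == parent)
                | (~tot.samples["genotype"].str.startswith("F0")))
            nfp = tmm_factors(sub)
            grp = np.where(sub.samples["genotype"].str.startswith("F0"),
                           "parent", "F1")
            dispp = glm.estimate_dispersions(
                sub.counts, _group_design(grp),
                offset=np.log(sub.lib_sizes().to_numpy()
                              * nfp.factors.to_numpy()),
                prior_df=prior_df)
            res = glm.nb_glm_test(
                sub.counts, grp,
                sub.lib_sizes().to_numpy() * nfp.factors.to_numpy(),
                dispp.trended, family=f"inherit_{parent}_{temp}",
                levels=["parent", "F1"])
            (res_o if parent == "F0_O" else res_s)[temp] = res
        calls = classify_inheritance(res_o[temp], res_s[temp],
                                     fold_threshold=fold_threshold,
                                     alpha=alpha)
        inh_calls[temp] = calls
        tests[(temp, "inherit_vs_O")] = res_o[temp]
        tests[(temp, "inherit_vs_S")] = res_s[temp]
        inh_rows.append(calls.assign(gene=calls.index, temperature=temp))

    temps = data.temperatures
    swapped = dominance_swapped(inh_calls[temps[0]], inh_calls[temps[-1]]) \
        if len(temps) >= 2 else []

    joint = glm.joint_temperature_model(data, prior_df=prior_df) \
        if run_joint else None

    return PipelineResult(
        regulatory=pd.concat(reg_rows, ignore_index=True),
        inheritance=pd.concat(inh_rows, ignore_index=True),
        swapped=swapped, imprinted=list(imp.flagged),
        expressed_mask=mask, tests=tests, joint=joint)


def _group_design(labels) -> np.ndarray:
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels))
    return np.column_stack([(labels == lv).astype(float) for lv in levels])
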