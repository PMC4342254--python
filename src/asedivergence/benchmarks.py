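"""Self-contained simulation benchmarks of the whole pipeline.

Each function simulates data under a stated architecture with the package's
own generator, runs the relevant analysis path end to end, and returns
summary metrics (type-I rates, FDR control, classification recovery,
assignment accuracy, ...).  The acceptance script and the acceptance test
suite both drive these entry points, so every reported number is recomputed
from scratch at call time.

Study conditions follow the generator defaults: 2,000 genes, four
temperatures, three replicates per channel, NB dispersion 0.1, mean counts
around 200-256 per channel, log-normal library-depth variation (CV 0.15).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (SimConfig, simulate_counts, null_dataset, simulate_reads,
               design_regulatory_architecture,
               design_inheritance_architecture,
               run_pipeline, joint_temperature_model, assign_read_pair,
               tmm_factors, downsample_rank_matched)

REGULATORY_PROPORTIONS = {"cis_only": 0.10, "trans_only": 0.10,
                          "cis_plus_trans": 0.05, "cis_x_trans": 0.05,
                          "compensatory": 0.05}
INHERITANCE_PROPORTIONS = {"O_dominant": 0.05, "S_dominant": 0.05,
                           "additive": 0.05, "over_dominant": 0.05,
                           "under_dominant": 0.05}
DEFINITE = ("cis_only", "trans_only", "cis_plus_trans", "cis_x_trans",
            "compensatory")
MEAN_LOG2 = float(np.log2(200))


def _child_seeds(seed, n):
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


# ------------------------------------------------------------------ criterion
def null_calibration(seed: int, n_genes: int = 2000) -> dict:
    """Raw p < 0.05 fraction of each test family on an all-null dataset."""
    table = null_dataset(SimConfig(n_genes=n_genes, seed=seed))
    res = run_pipeline(table, run_joint=True)
    out = {}
    for fam in ("F0", "F1", "T"):
        ps = np.concatenate([res.tests[(t, fam)]["p"].to_numpy()
                             for t in table.temperatures])
        out[fam] = float(np.nanmean(ps < 0.05))
    out["interaction"] = float(
        np.nanmean(res.joint["ratio_interaction"]["p"] < 0.05))
    return out


def fdr_control(seed: int, n_seeds: int = 20, n_genes: int = 2000) -> dict:
    """Mean FDP among BH-called genes on signal-bearing datasets.

    For the per-temperature F0 / F1 / T families the data carry the
    designed regulatory architecture; a gene is a true null for a family
    when its generative effect for that family's hypothesis is zero
    (c + r = 0 for F0, c = 0 for F1, r = 0 for T).  For the
    temperature-interaction family, a fifth of the genes get a trans effect
    that changes across temperatures.  FDP = (null calls) / (all calls),
    zero when nothing is called, averaged over ``n_seeds`` datasets.
    """
    fdps = {"F0": [], "F1": [], "T": [], "interaction": []}
    for s in _child_seeds(seed, n_seeds):
        c, r, _ = design_regulatory_architecture(
            n_genes, proportions=REGULATORY_PROPORTIONS, effect=2.0, seed=s)
        table, truth = simulate_counts(SimConfig(
            n_genes=n_genes, cis=c, trans=r, seed=s,
            baseline_log2_mean=MEAN_LOG2))
        res = run_pipeline(table)
        gt0 = truth.df[truth.df["temperature"] == table.temperatures[0]]
        gt0 = gt0.set_index("gene")
        null_of = {"F0": (gt0["cis"] + gt0["trans"]) == 0,
                   "F1": gt0["cis"] == 0,
                   "T": gt0["trans"] == 0}
        for fam in ("F0", "F1", "T"):
            V = R = 0
            for temp in table.temperatures:
                t = res.tests[(temp, fam)]
                called = t.index[t["fdr"] <= 0.05]
                R += len(called)
                V += int(null_of[fam].reindex(called).sum())
            fdps[fam].append(V / max(R, 1))

        # interaction: trans effect varies across temperature for 20%
        ci, ri, labi = design_regulatory_architecture(
            n_genes, proportions={"trans_only": 0.2}, effect=2.0, seed=s)
        ri = ri * np.array([1.0, 0.0, 0.5, -1.0])
        ti, _ = simulate_counts(SimConfig(
            n_genes=n_genes, cis=ci, trans=ri, seed=s,
            baseline_log2_mean=MEAN_LOG2))
        jm = joint_temperature_model(ti)
        resi = jm["ratio_interaction"]
        called = resi.index[resi["fdr"] <= 0.05]
        is_null = pd.Series(labi != "trans_only",
                            index=ti.genes).reindex(called)
        fdps["interaction"].append(int(is_null.sum()) / max(len(called), 1))
    return {fam: float(np.mean(v)) for fam, v in fdps.items()}


def category_recovery(seed: int, n_genes: int = 2000,
                      temperature=None) -> dict:
    """Fraction of each designed regulatory class receiving its label."""
    c, r, _ = design_regulatory_architecture(
        n_genes, proportions=REGULATORY_PROPORTIONS, effect=2.0, seed=seed)
    table, truth = simulate_counts(SimConfig(
        n_genes=n_genes, cis=c, trans=r, seed=seed,
        baseline_log2_mean=MEAN_LOG2))
    res = run_pipeline(table)
    temperature = temperature or table.temperatures[0]
    reg = res.regulatory[res.regulatory["temperature"] == temperature]
    reg = reg.set_index("gene")
    labels = truth.category(temperature).reindex(reg.index)
    out = {}
    for cat in DEFINITE:
        sel = labels == cat
        out[cat] = float((reg["category"][sel] == cat).mean())
    nulls = labels == "not_different"
    out["null_to_definite"] = float(
        reg["category"][nulls].isin(DEFINITE).mean())
    return out


def inheritance_recovery(seed: int, n_genes: int = 2000) -> dict:
    """Mode recovery, dominance-swap detection, and false-swap rate."""
    r, d, labels = design_inheritance_architecture(
        n_genes, proportions=INHERITANCE_PROPORTIONS, swap_fraction=0.05,
        seed=seed)
    table, truth = simulate_counts(SimConfig(
        n_genes=n_genes, trans=r, f1_offset=d, seed=seed,
        baseline_log2_mean=MEAN_LOG2))
    res = run_pipeline(table)
    temp = table.temperatures[0]
    inh = res.inheritance[res.inheritance["temperature"] == temp]
    inh = inh.set_index("gene")
    gt_modes = truth.mode(temp).reindex(inh.index)
    out = {}
    for mode in INHERITANCE_PROPORTIONS:
        designed = pd.Series(labels == mode, index=table.genes)
        sel = designed.reindex(inh.index).fillna(False) & (gt_modes == mode)
        out[mode] = float((inh["mode"][sel] == mode).mean())
    true_swap = set(truth.swapped_genes)
    called = set(res.swapped)
    out["swap_recovery"] = len(true_swap & called) / max(len(true_swap), 1)
    nonswap_dom = {g for g, lab in zip(table.genes, labels)
                   if lab in ("O_dominant", "S_dominant")}
    out["false_swap_rate"] = (len(nonswap_dom & called)
                              / max(len(nonswap_dom), 1))
    return out


def effect_identity_error(seed: int, n_genes: int = 500) -> float:
    """Max |e_cis + e_trans - log2(F0_O/F0_S)| over genes and temperatures."""
    c, r, _ = design_regulatory_architecture(
        n_genes, proportions=REGULATORY_PROPORTIONS, effect=2.0, seed=seed)
    table, _ = simulate_counts(SimConfig(
        n_genes=n_genes, cis=c, trans=r, seed=seed,
        baseline_log2_mean=MEAN_LOG2))
    res = run_pipeline(table)
    worst = 0.0
    for temp in table.temperatures:
        at = table.at_temperature(temp)
        sub = res.regulatory[res.regulatory["temperature"] == temp]
        sub = sub.set_index("gene")
        nf = tmm_factors(at)
        eff = at.lib_sizes() * nf.factors
        norm = at.counts.loc[sub.index].div(eff, axis=1)
        ch = at.samples["channel"]
        f0o = norm[ch.index[ch == "F0_O"]].mean(axis=1)
        f0s = norm[ch.index[ch == "F0_S"]].mean(axis=1)
        err = np.abs(sub["e_cis"] + sub["e_trans"] - np.log2(f0o / f0s))
        worst = max(worst, float(err.max()))
    return worst


def assignment_accuracy(seed: int, n_pairs: int = 20000) -> dict:
    """Error-free assignment accuracy and label conservation."""
    cfg = SimConfig(n_genes=50, seed=seed)
    genomes, _, pairs, _ = simulate_reads(cfg, snp_rate=0.005,
                                          error_rate=0.0, n_pairs=n_pairs)
    labels = [assign_read_pair(p, genomes) for p in pairs]
    assigned = sum(1 for lab in labels if lab in ("O", "S"))
    correct = sum(1 for p, lab in zip(pairs, labels)
                  if lab in ("O", "S") and lab == p.true_hap)
    conserved = (sum(1 for lab in labels
                     if lab in ("O", "S", "ambiguous", "unmapped"))
                 == len(pairs))
    return {"accuracy": correct / max(assigned, 1),
            "n_assigned": assigned,
            "conserved": conserved}


def bias_screen_rates(seed: int, n_seeds: int = 20) -> dict:
    """Symmetric-gene pass rate and asymmetric-assigner detection rate."""
    from .assign import GeneAnnotation, SnpSet, build_parental_genomes, \
        mapping_bias_screen

    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list("ACGT"), size=3000))
    genes = pd.DataFrame(
        [("gA", "c1", 100, 1100, "+"), ("gC", "c1", 2000, 2900, "+")],
        columns=["gene_id", "chrom", "start", "end", "strand"])
    annotation = GeneAnnotation(genes=genes.copy())

    def alt(base):
        return "A" if base != "A" else "C"

    snp_rows = [("c1", pos, ref[pos - 1], alt(ref[pos - 1]), parent)
                for pos, parent in
                [(301, "O"), (601, "S"), (2101, "O"), (2501, "S")]]
    snps = SnpSet(pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "ref", "alt", "parent"]))
    genomes = build_parental_genomes({"c1": ref}, snps)
    hole = (250, 450)

    def holey(pair, g):
        lo, hi = pair.span
        label = assign_read_pair(pair, g)
        if lo < hole[1] and hi > hole[0] and pair.true_hap == "S":
            return "unmapped" if label in ("S", "ambiguous") else label
        return label

    sym_pass = asym_flag = 0
    for s in _child_seeds(seed + 1, n_seeds):
        clean = mapping_bias_screen(genomes, annotation, n_pairs=200, seed=s)
        sym_pass += int(clean.biased == [])
        holed = mapping_bias_screen(genomes, annotation, n_pairs=200, seed=s,
                                    assign_fn=holey)
        asym_flag += int("gA" in holed.biased and "gC" not in holed.biased)
    return {"symmetric_pass_rate": sym_pass / n_seeds,
            "asymmetric_detect_rate": asym_flag / n_seeds}


def downsampling_check(seed: int, n_draws: int = 1000) -> dict:
    """Exact target totals plus hypergeometric-mean agreement (2 SE)."""
    from .tables import AlleleCountTable, build_sample_frame

    sm = build_sample_frame(("23C",), 1)
    two = sm[sm["channel"].isin(["F0_O", "F0_S"])]
    counts = pd.DataFrame(
        {two.index[0]: [600, 400], two.index[1]: [250, 250]},
        index=["g1", "g2"])
    draws = []
    exact = True
    for s in _child_seeds(seed, n_draws):
        t = AlleleCountTable(counts.copy(), two.copy())
        d = downsample_rank_matched(t, seed=s)
        col = d.counts[two.index[0]]
        exact &= int(col.sum()) == 500
        draws.append(col.to_numpy())
    draws = np.array(draws)
    mean = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1) / np.sqrt(n_draws)
    within = bool(abs(mean[0] - 300) < 2 * se[0] + 1e-9
                  and abs(mean[1] - 200) < 2 * se[1] + 1e-9)
    return {"totals_exact": exact, "mean_within_2se": within,
            "mean_g1": float(mean[0])}
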