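import numpy as np
import pandas as pd
import pytest

import asedivergence as ad


@pytest.fixture(scope="session")
def null_table_small():
    """Null 300-gene table reused by calibration-independent tests."""
    return ad.null_dataset(ad.SimConfig(n_genes=300, seed=42))


@pytest.fixture(scope="session")
def designed_run():
    """One shared pipeline run on a designed regulatory architecture."""
    c, r, labels = ad.design_regulatory_architecture(
        800, proportions={"cis_only": 0.10, "trans_only": 0.10,
                          "cis_plus_trans": 0.05, "cis_x_trans": 0.05,
                          "compensatory": 0.05},
        effect=2.0, seed=11)
    cfg = ad.SimConfig(n_genes=800, cis=c, trans=r, seed=11,
                       baseline_log2_mean=np.log2(200))
    table, truth = ad.simulate_counts(cfg)
    result = ad.run_pipeline(table)
    return table, truth, result, labels


@pytest.fixture()
def tiny_genome_setup():
    """Reference, two overlapping + one isolated gene, diagnostic SNPs."""
    rng = np.random.default_rng(1)
    ref = "".join(rng.choice(list("ACGT"), size=3000))
    genes = pd.DataFrame(
        [("gA", "c1", 100, 1100, "+"),
         ("gB", "c1", 900, 1900, "+"),
         ("gC", "c1", 2000, 2900, "-")],
        columns=["gene_id", "chrom", "start", "end", "strand"])
    annotation = ad.GeneAnnotation(genes=genes.copy())

    def alt(base):
        return "A" if base != "A" else "C"

    snp_rows = [("c1", pos, ref[pos - 1], alt(ref[pos - 1]), parent)
                for pos, parent in
                [(301, "O"), (601, "S"), (1501, "O"), (2101, "O"),
                 (2501, "S")]]
    snps = ad.SnpSet(pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "ref", "alt", "parent"]))
    genomes = ad.build_parental_genomes({"c1": ref}, snps)
    return ref, annotation, snps, genomes
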