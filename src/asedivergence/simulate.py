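"""Synthetic allele-specific expression data with known regulatory truth.

The generator emulates the measurement design of a two-strain (Oregon R "O"
and Samarkand "S") cross experiment: for each gene g and environment
(temperature) t it fixes a cis effect ``c`` and a trans effect ``r`` in
log2 units plus an optional F1 total-level offset ``d``, and constructs
channel means

    mu_F0O = 2^(b + (c + r) / 2)      mu_F1O = 2^(b + d + c / 2)
    mu_F0S = 2^(b - (c + r) / 2)      mu_F1S = 2^(b + d - c / 2)

so that log2(mu_F0O / mu_F0S) = c + r and log2(mu_F1O / mu_F1S) = c exactly.
Counts are independent negative-binomial draws around these means scaled by
per-library size multipliers.  The returned :class:`GroundTruth` records the
exact parameters together with the regulatory category and inheritance mode
they imply, which is what the acceptance surface of the downstream
classifiers scores against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assign import GeneAnnotation, GenomePair, ReadPair, SnpSet
from .tables import AlleleCountTable, build_sample_frame

__all__ = ["SimConfig", "GroundTruth", "simulate_counts", "null_dataset",
           "simulate_reads", "design_regulatory_architecture",
           "design_inheritance_architecture"]

DEFAULT_TEMPERATURES = ("13C", "18C", "23C", "29C")

CATEGORIES = ("not_different", "cis_only", "trans_only", "cis_plus_trans",
              "cis_x_trans", "compensatory")
MODES = ("not_different", "O_dominant", "S_dominant", "additive",
         "over_dominant", "under_dominant")

_FOLD = np.log2(1.25)  # divergence threshold used for ground-truth modes


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    ``cis``, ``trans`` and ``f1_offset`` are (n_genes x n_temperatures)
    arrays of log2-scale effects; scalars broadcast.  ``dispersion`` is the
    NB dispersion phi (variance = mu + phi mu^2), scalar or per-gene.
    ``library_size_cv`` is the coefficient of variation of the lognormal
    per-library depth multipliers; explicit multipliers (one per physical
    library, in sample-sheet order) override it.  A "mito-like" gene with an
    extreme, opposite allelic imbalance in the two reciprocal crosses can be
    appended to exercise the imprinting screen.
    """

    n_genes: int = 2000
    temperatures: tuple = DEFAULT_TEMPERATURES
    n_replicates: int = 3
    baseline_log2_mean: float | np.ndarray = 8.0
    dispersion: float | np.ndarray = 0.1
    library_size_cv: float = 0.15
    library_size_multipliers: np.ndarray | None = None
    cis: float | np.ndarray = 0.0
    trans: float | np.ndarray = 0.0
    f1_offset: float | np.ndarray = 0.0
    mito_like_gene: bool = False
    mito_fraction: float = 0.9999
    mito_log2_mean: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 1:
            raise ValueError("at least one replicate per channel is required")
        if not self.temperatures:
            raise ValueError("at least one temperature is required")
        for name in ("cis", "trans", "f1_offset", "baseline_log2_mean"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        phi = np.asarray(self.dispersion, dtype=float)
        if np.any(phi < 0):
            raise ValueError("dispersion must be >= 0")
        if self.library_size_multipliers is not None:
            m = np.asarray(self.library_size_multipliers, dtype=float)
            if np.any(m <= 0):
                raise ValueError("library multipliers must be positive")

    def _grid(self, value) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(value, dtype=float),
            (self.n_genes, len(self.temperatures))).copy()

    @classmethod
    def sample_gamma_dispersions(cls, n_genes, shape=2.0, mean=0.1, seed=0):
        """Per-gene dispersions drawn from a gamma with the given mean."""
        rng = np.random.default_rng(seed)
        return rng.gamma(shape, mean / shape, size=n_genes)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact per-gene, per-temperature generative parameters and labels.

    ``df`` has one row per (gene, temperature) with the effects, channel
    means, the implied regulatory category, and the implied inheritance
    mode; ``swapped_genes`` lists genes dominant for opposite parents at the
    two extreme temperatures.
    """

    df: pd.DataFrame
    temperatures: tuple

    def category(self, temperature) -> pd.Series:
        sub = self.df[self.df["temperature"] == temperature]
        return sub.set_index("gene")["category"]

    def mode(self, temperature) -> pd.Series:
        sub = self.df[self.df["temperature"] == temperature]
        return sub.set_index("gene")["inheritance_mode"]

    @property
    def swapped_genes(self) -> list:
        lo = self.mode(self.temperatures[0])
        hi = self.mode(self.temperatures[-1])
        swap = ((lo == "O_dominant") & (hi == "S_dominant")) | \
               ((lo == "S_dominant") & (hi == "O_dominant"))
        return list(lo.index[swap])

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)


def _implied_category(c, r):
    if c == 0 and r == 0:
        return "not_different"
    if r == 0:
        return "cis_only"
    if c == 0:
        return "trans_only"
    if c + r == 0:
        return "compensatory"
    return "cis_plus_trans" if np.sign(c) == np.sign(r) else "cis_x_trans"


def _implied_mode(c, r, d):
    """Mode of inheritance implied by the construction.

    Levels are taken relative to a normalization that absorbs the factor-2
    total of the two F1 allele channels: parents sit at +-(c + r)/2 around
    the baseline and the F1 total at d + log2(cosh-like allele sum).
    """
    delta = c + r
    lo_p = delta / 2.0
    ls_p = -delta / 2.0
    f1 = d + np.log2((2.0 ** (c / 2.0) + 2.0 ** (-c / 2.0)) / 2.0)
    div_o = abs(f1 - lo_p) > _FOLD
    div_s = abs(f1 - ls_p) > _FOLD
    if not div_o and not div_s:
        return "not_different"
    if div_s and not div_o:
        return "O_dominant"
    if div_o and not div_s:
        return "S_dominant"
    lo_hi = max(lo_p, ls_p)
    lo_lo = min(lo_p, ls_p)
    if f1 > lo_hi:
        return "over_dominant"
    if f1 < lo_lo:
        return "under_dominant"
    return "additive"


# --------------------------------------------------------------------------
# architecture designers
# --------------------------------------------------------------------------

def design_regulatory_architecture(n_genes, temperatures=DEFAULT_TEMPERATURES,
                                   proportions=None, effect=2.0, seed=0):
    """Assign regulatory categories to genes and return (cis, trans) grids.

    ``proportions`` maps category -> fraction of genes (remainder is
    ``not_different``).  Effects are constant across temperatures with a
    random sign per gene; ``cis_x_trans`` genes get an opposing trans effect
    of twice the magnitude so the parental divergence does not cancel.
    """
    props = dict(proportions or {})
    other = sum(props.values())
    if other > 1 + 1e-9:
        raise ValueError("category proportions sum to more than 1")
    props["not_different"] = max(0.0, 1.0 - other)
    unknown = set(props) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    counts = {k: int(round(v * n_genes)) for k, v in props.items()}
    labels = [k for k, n in counts.items() for _ in range(n)]
    labels = (labels + ["not_different"] * n_genes)[:n_genes]
    rng.shuffle(labels)

    T = len(temperatures)
    c = np.zeros((n_genes, T))
    r = np.zeros((n_genes, T))
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    for g, lab in enumerate(labels):
        e = sign[g] * effect
        if lab == "cis_only":
            c[g, :] = e
        elif lab == "trans_only":
            r[g, :] = e
        elif lab == "cis_plus_trans":
            c[g, :] = e
            r[g, :] = e
        elif lab == "cis_x_trans":
            c[g, :] = e
            r[g, :] = -2.0 * e
        elif lab == "compensatory":
            c[g, :] = e
            r[g, :] = -e
    return c, r, np.array(labels)


def design_inheritance_architecture(n_genes, temperatures=DEFAULT_TEMPERATURES,
                                    proportions=None, parent_log2_fold=3.0,
                                    swap_fraction=0.0, seed=0):
    """Assign inheritance modes and return (trans, f1_offset) grids.

    Parental divergence is placed entirely in trans (``c = 0``) at
    ``parent_log2_fold`` log2 units; the F1 offset ``d`` positions the F1
    total at the parent level (dominance), midpoint (additive), or outside
    the parental range (over-/under-dominance).  ``swap_fraction`` genes are
    S-dominant at the first temperature and O-dominant at the last.
    """
    props = dict(proportions or {})
    rng = np.random.default_rng(seed)
    delta = parent_log2_fold
    T = len(temperatures)

    n_swap = int(round(swap_fraction * n_genes))
    counts = {k: int(round(v * n_genes)) for k, v in props.items()}
    labels = [k for k, n in counts.items() for _ in range(n)]
    labels = ["swapped"] * n_swap + labels
    labels = (labels + ["not_different"] * n_genes)[:n_genes]
    rng.shuffle(labels)

    d_for = {"O_dominant": delta / 2.0, "S_dominant": -delta / 2.0,
             "additive": 0.0, "over_dominant": delta / 2.0 + 1.0,
             "under_dominant": -delta / 2.0 - 1.0}

    r = np.zeros((n_genes, T))
    d = np.zeros((n_genes, T))
    for g, lab in enumerate(labels):
        if lab == "not_different":
            continue
        r[g, :] = delta
        if lab == "swapped":
            d[g, :] = np.linspace(-delta / 2.0, delta / 2.0, T)
        else:
            d[g, :] = d_for[lab]
    return r, d, np.array(labels)


# --------------------------------------------------------------------------
# count simulation
# --------------------------------------------------------------------------

def _nb_draw(rng, mean, phi):
    """NB(mean, dispersion phi) via gamma-Poisson; phi == 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        lam = rng.gamma(1.0 / phi[~pois], phi[~pois] * mean[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def simulate_counts(config: SimConfig):
    """Draw an :class:`AlleleCountTable` and its :class:`GroundTruth`."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    G, T = cfg.n_genes, len(cfg.temperatures)
    c = cfg._grid(cfg.cis)
    r = cfg._grid(cfg.trans)
    d = cfg._grid(cfg.f1_offset)
    b = np.broadcast_to(np.asarray(cfg.baseline_log2_mean, dtype=float),
                        (G,)).copy()
    phi = np.broadcast_to(np.asarray(cfg.dispersion, dtype=float), (G,)).copy()

    genes = [f"g{i:05d}" for i in range(G)]
    samples = build_sample_frame(cfg.temperatures, cfg.n_replicates)

    # one depth multiplier per physical library, shared by paired channels
    lib_keys = list(dict.fromkeys(
        zip(samples["genotype"], samples["temperature"],
            samples["replicate"])))
    if cfg.library_size_multipliers is not None:
        mult = np.asarray(cfg.library_size_multipliers, dtype=float)
        if mult.size != len(lib_keys):
            raise ValueError(
                f"expected {len(lib_keys)} library multipliers, "
                f"got {mult.size}")
    else:
        sigma = np.sqrt(np.log1p(cfg.library_size_cv ** 2))
        mult = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=len(lib_keys))
    mult_of = dict(zip(lib_keys, mult))

    mu = {
        "F0_O": 2.0 ** (b[:, None] + (c + r) / 2.0),
        "F0_S": 2.0 ** (b[:, None] - (c + r) / 2.0),
        "F1_O": 2.0 ** (b[:, None] + d + c / 2.0),
        "F1_S": 2.0 ** (b[:, None] + d - c / 2.0),
    }

    mito = None
    if cfg.mito_like_gene:
        mito = "mito_like"
        genes.append(mito)
        G += 1
        b = np.append(b, cfg.mito_log2_mean)
        phi = np.append(phi, np.median(phi))
        c = np.vstack([c, np.zeros(T)])
        r = np.vstack([r, np.zeros(T)])
        d = np.vstack([d, np.zeros(T)])
        tot = 2.0 ** cfg.mito_log2_mean
        for key in mu:
            mu[key] = np.vstack([mu[key], np.full(T, tot / 2.0)])

    cols = {}
    t_index = {t: k for k, t in enumerate(cfg.temperatures)}
    for sid, row in samples.iterrows():
        t = t_index[row["temperature"]]
        m = mult_of[(row["genotype"], row["temperature"], row["replicate"])]
        if row["genotype"].startswith("F0"):
            mean = mu[row["channel"]][:, t] * m
        else:
            mean = mu[f"F1_{row['allele']}"][:, t] * m
            if mito is not None:
                frac = cfg.mito_fraction
                p = frac if row["allele"] == "O" else 1.0 - frac
                if row["genotype"] == "F1B":
                    p = 1.0 - p
                mean = mean.copy()
                mean[-1] = 2.0 ** cfg.mito_log2_mean * p * m
        cols[sid] = _nb_draw(rng, mean, phi)

    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    table = AlleleCountTable(counts, samples.copy())

    rows = []
    for t, temp in enumerate(cfg.temperatures):
        for g, gene in enumerate(genes):
            rows.append((gene, temp, c[g, t], r[g, t], d[g, t],
                         _implied_category(c[g, t], r[g, t]),
                         _implied_mode(c[g, t], r[g, t], d[g, t]),
                         mu["F0_O"][g, t], mu["F0_S"][g, t],
                         mu["F1_O"][g, t], mu["F1_S"][g, t]))
    gt = pd.DataFrame(rows, columns=[
        "gene", "temperature", "cis", "trans", "f1_offset", "category",
        "inheritance_mode", "mu_F0_O", "mu_F0_S", "mu_F1_O", "mu_F1_S"])
    return table, GroundTruth(df=gt, temperatures=tuple(cfg.temperatures))


def null_dataset(config: SimConfig) -> AlleleCountTable:
    """Same design with all effects zeroed — the type-I-error harness."""
    cfg = replace(config, cis=0.0, trans=0.0, f1_offset=0.0,
                  mito_like_gene=False)
    table, _ = simulate_counts(cfg)
    return table


# --------------------------------------------------------------------------
# genome + read simulation
# --------------------------------------------------------------------------

def simulate_reads(config: SimConfig, snp_rate: float, read_length: int = 75,
                   error_rate: float = 0.0, gene_length: int = 2000,
                   spacer: int = 500, fragment_length: int = 250,
                   n_pairs: int = 20000):
    """Generate parental genomes, an annotation, and tagged read pairs.

    One chromosome carries ``config.n_genes`` genes of ``gene_length`` bases
    separated by ``spacer``.  The O genome equals the generated reference;
    the S genome substitutes a random alternative base at each SNP site
    (density ``snp_rate`` per base, genome-wide).  Read pairs are sampled
    from the gene bodies of each parental haplotype in proportion to the
    parental channel means of :func:`simulate_counts` at the first
    temperature; each pair's name and ``true_hap`` tag record its origin.

    Returns ``(GenomePair, GeneAnnotation, list[ReadPair], SnpSet)``.
    """
    if not 0 <= snp_rate < 1:
        raise ValueError("snp_rate must lie in [0, 1)")
    if gene_length < fragment_length:
        raise ValueError("genes must be at least one fragment long")
    if read_length >= gene_length:
        raise ValueError("read_length must be smaller than gene length")

    ss = np.random.SeedSequence(config.seed).spawn(3)
    rng_genome, rng_reads, rng_err = (np.random.default_rng(s) for s in ss)

    chrom = "chr2L"
    G = config.n_genes
    length = G * (gene_length + spacer) + spacer
    ref = rng_genome.choice(list("ACGT"), size=length)

    rows = []
    for g in range(G):
        start = spacer + g * (gene_length + spacer)
        rows.append((f"g{g:05d}", chrom, start, start + gene_length,
                     "+" if g % 2 == 0 else "-"))
    annotation = GeneAnnotation(genes=pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]))

    n_snps = int(round(snp_rate * length))
    snp_pos = np.sort(rng_genome.choice(length, size=n_snps, replace=False)) \
        if n_snps else np.array([], dtype=int)
    s_seq = ref.copy()
    snp_rows = []
    for i in snp_pos:
        refbase = ref[i]
        alt = rng_genome.choice([x for x in "ACGT" if x != refbase])
        s_seq[i] = alt
        snp_rows.append((chrom, int(i) + 1, refbase, alt, "S"))
    snps = SnpSet(pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "ref", "alt", "parent"]))
    genomes = GenomePair(o={chrom: "".join(ref)}, s={chrom: "".join(s_seq)})

    # sampling weights from the parental generative means, first temperature
    c = config._grid(config.cis)[:, 0]
    r = config._grid(config.trans)[:, 0]
    b = np.broadcast_to(np.asarray(config.baseline_log2_mean, float), (G,))
    w_o = 2.0 ** (b + (c + r) / 2.0)
    w_s = 2.0 ** (b - (c + r) / 2.0)
    weights = np.concatenate([w_o, w_s])
    weights = weights / weights.sum()
    picks = rng_reads.choice(2 * G, size=n_pairs, p=weights)

    def with_errors(seq: str) -> str:
        if error_rate <= 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        hits = np.nonzero(rng_err.random(arr.size) < error_rate)[0]
        for i in hits:
            arr[i] = rng_err.choice([x for x in "ACGT" if x != arr[i]])
        return "".join(arr)

    ann = annotation.genes
    pairs = []
    for k, pick in enumerate(picks):
        g = pick % G
        hap = "O" if pick < G else "S"
        genome = genomes.o if hap == "O" else genomes.s
        row = ann.iloc[g]
        frag = int(rng_reads.integers(row["start"],
                                      row["end"] - fragment_length + 1))
        seq = genome[chrom]
        s1 = frag
        s2 = frag + fragment_length - read_length
        pairs.append(ReadPair(
            name=(f"pair{k}|{row['gene_id']}|{hap}|{chrom}|{frag}"
                  f"|{frag + fragment_length}"),
            chrom=chrom,
            start1=s1, seq1=with_errors(seq[s1:s1 + read_length]),
            start2=s2, seq2=with_errors(seq[s2:s2 + read_length]),
            true_hap=hap, true_gene=row["gene_id"]))
    return genomes, annotation, pairs, snps
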