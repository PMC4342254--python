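"""Count-table container shared by the whole pipeline.

An :class:`AlleleCountTable` couples a genes x samples integer count matrix
with per-sample metadata describing which measurement channel each library
column represents.  Six channels exist: the two inbred parents (``F0_O``,
``F0_S``) and, for each reciprocal F1 cross (``F1A``, ``F1B``), the reads
assigned to the Oregon-R-derived allele (``_O``) and to the Samarkand-derived
allele (``_S``).  The two allele channels of one F1 library always come from
the same physical library and therefore share a replicate index and library
scale.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: genotype -> channels it contributes
GENOTYPES = ("F0_O", "F0_S", "F1A", "F1B")
CHANNELS = ("F0_O", "F0_S", "F1A_O", "F1A_S", "F1B_O", "F1B_S")

_META_COLUMNS = ["channel", "genotype", "allele", "temperature", "replicate"]


@dataclass
class AlleleCountTable:
    """Genes x samples allele-specific count matrix with sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, index = gene ids, columns = sample ids.
    samples
        One row per sample (same order as ``counts`` columns) with columns
        ``channel``, ``genotype``, ``allele``, ``temperature``, ``replicate``
        and optionally ``lib_size``.  Missing library sizes default to the
        column sums.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and samples index must match")
        missing = [c for c in _META_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"samples metadata lacks columns: {missing}")
        bad = set(self.samples["channel"]) - set(CHANNELS)
        if bad:
            raise ValueError(f"unknown channels: {sorted(bad)}")
        arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if "lib_size" not in self.samples.columns:
            self.samples = self.samples.copy()
            self.samples["lib_size"] = arr.sum(axis=0)

    # ------------------------------------------------------------------ views
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def temperatures(self) -> list:
        seen: list = []
        for t in self.samples["temperature"]:
            if t not in seen:
                seen.append(t)
        return seen

    def lib_sizes(self) -> pd.Series:
        return self.samples["lib_size"].astype(float)

    def subset_samples(self, mask) -> "AlleleCountTable":
        sub = self.samples.loc[mask]
        return AlleleCountTable(self.counts[sub.index], sub.copy())

    def at_temperature(self, temperature) -> "AlleleCountTable":
        return self.subset_samples(self.samples["temperature"] == temperature)

    def channel(self, *channels: str) -> "AlleleCountTable":
        return self.subset_samples(self.samples["channel"].isin(channels))

    def subset_genes(self, genes) -> "AlleleCountTable":
        return AlleleCountTable(self.counts.loc[genes], self.samples.copy())

    def f1_totals(self) -> "AlleleCountTable":
        """Collapse the paired F1 allele channels into per-library totals.

        F0 columns are kept as they are.  The returned table has one column
        per physical library, which is what the mode-of-inheritance tests
        operate on.
        """
        cols = {}
        meta_rows = []
        for sid, row in self.samples.iterrows():
            if row["genotype"].startswith("F0"):
                cols[sid] = self.counts[sid]
                meta_rows.append((sid, row["channel"], row["genotype"],
                                  row["allele"], row["temperature"],
                                  row["replicate"]))
        f1 = self.samples[~self.samples["genotype"].str.startswith("F0")]
        for (gt, temp, rep), grp in f1.groupby(
                ["genotype", "temperature", "replicate"], sort=False):
            sid = f"{gt}_{temp}_r{rep}"
            cols[sid] = self.counts[grp.index].sum(axis=1)
            # totals are genotype-level; reuse the O-channel label slot
            meta_rows.append((sid, f"{gt}_O", gt, "both", temp, rep))
        counts = pd.DataFrame(cols)
        meta = pd.DataFrame(
            meta_rows,
            columns=["sample"] + _META_COLUMNS).set_index("sample")
        meta["channel"] = [c if c in CHANNELS else c for c in meta["channel"]]
        return AlleleCountTable(counts, meta)

    # -------------------------------------------------------------------- io
    def to_tsv(self, path) -> None:
        """Write counts with a ``#``-prefixed metadata header block."""
        with open(path, "w") as fh:
            for col in _META_COLUMNS + ["lib_size"]:
                vals = "\t".join(str(v) for v in self.samples[col])
                fh.write(f"#{col}\t{vals}\n")
            self.counts.rename_axis("gene").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountTable":
        meta: dict[str, list[str]] = {}
        body = io.StringIO()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, *vals = line[1:].rstrip("\n").split("\t")
                    meta[key] = vals
                else:
                    body.write(line)
        body.seek(0)
        counts = pd.read_csv(body, sep="\t", index_col=0)
        samples = pd.DataFrame(meta, index=counts.columns)
        samples["replicate"] = samples["replicate"].astype(int)
        samples["lib_size"] = samples["lib_size"].astype(float)
        return cls(counts, samples)


def build_sample_frame(temperatures, n_replicates) -> pd.DataFrame:
    """Canonical sample sheet for a full four-genotype design."""
    rows = []
    for temp in temperatures:
        for rep in range(1, n_replicates + 1):
            rows.append((f"F0_O_{temp}_r{rep}", "F0_O", "F0_O", "O", temp, rep))
            rows.append((f"F0_S_{temp}_r{rep}", "F0_S", "F0_S", "S", temp, rep))
            for gt in ("F1A", "F1B"):
                for allele in ("O", "S"):
                    rows.append((f"{gt}_{allele}_{temp}_r{rep}",
                                 f"{gt}_{allele}", gt, allele, temp, rep))
    return pd.DataFrame(
        rows, columns=["sample"] + _META_COLUMNS).set_index("sample")
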