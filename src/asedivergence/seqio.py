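"""FASTA/FASTQ round-trips for genomes and simulated read pairs.

Read-pair names carry the fields the exact matcher needs to relocate a pair
(``name|gene|hap|chrom|fragstart``); mate 2 is written reverse-complemented,
as a sequencer would emit it, and flipped back on reading.
"""

from __future__ import annotations

import gzip

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assign import ReadPair

__all__ = ["write_fasta", "read_fasta", "write_fastq_pairs",
           "read_fastq_pairs"]


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def _open(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pairs(pairs, path1, path2, quality: int = 40) -> None:
    with _open(path1, "w") as fh1, _open(path2, "w") as fh2:
        for pair in pairs:
            r1 = SeqRecord(Seq(pair.seq1), id=pair.name, description="")
            r1.letter_annotations["phred_quality"] = [quality] * len(pair.seq1)
            r2 = SeqRecord(Seq(pair.seq2).reverse_complement(),
                           id=pair.name, description="")
            r2.letter_annotations["phred_quality"] = [quality] * len(pair.seq2)
            SeqIO.write([r1], fh1, "fastq")
            SeqIO.write([r2], fh2, "fastq")


def read_fastq_pairs(path1, path2) -> list:
    """Rebuild located :class:`ReadPair` objects from a FASTQ pair."""
    pairs = []
    with _open(path1, "r") as fh1, _open(path2, "r") as fh2:
        for r1, r2 in zip(SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq")):
            if r1.id != r2.id:
                raise ValueError(f"mate name mismatch: {r1.id} vs {r2.id}")
            try:
                _, gene, hap, chrom, frag, frag_end = r1.id.split("|")
                frag, frag_end = int(frag), int(frag_end)
            except ValueError as exc:
                raise ValueError(
                    f"read name {r1.id!r} lacks locus fields") from exc
            seq1 = str(r1.seq)
            seq2 = str(r2.seq.reverse_complement())
            if not seq1 or not seq2:
                raise ValueError("zero-length mate in FASTQ input")
            # mate 1 starts the fragment; mate 2 is flush with its end
            pairs.append(ReadPair(
                name=r1.id, chrom=chrom,
                start1=frag, seq1=seq1,
                start2=frag_end - len(seq2), seq2=seq2,
                true_hap=hap, true_gene=gene))
    return pairs
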