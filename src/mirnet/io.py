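"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; GFF3 features use 1-based inclusive
coordinates per the format, converted from the library's 0-based half-open
intervals here and nowhere else.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GenomicInterval, MirnaLocus, Pwm, ReadStack


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike,
                quality_char: str = "I") -> None:
    """Write (read id, sequence) pairs with a constant placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_collapsed_fasta(stacks: Iterable[ReadStack], path: str | os.PathLike) -> None:
    """Collapsed sRNA FASTA with ``>seq<N>_<count>`` headers (total counts)."""
    with open(path, "w") as fh:
        for i, st in enumerate(stacks, 1):
            fh.write(f">seq{i}_{st.total_count}\n{st.sequence}\n")


def read_collapsed_fasta(path: str | os.PathLike,
                         library: str = "lib") -> list[ReadStack]:
    stacks = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_", 1)[1])
        stacks.append(ReadStack(str(rec.seq), {library: count}))
    return stacks


# ----------------------------------------------------------------------- GFF3

def _gff_line(chrom: str, source: str, ftype: str, iv: GenomicInterval,
              attrs: str) -> str:
    return "\t".join([chrom, source, ftype, str(iv.start + 1), str(iv.end),
                      ".", iv.strand, ".", attrs])


def write_loci_gff(loci: Iterable[MirnaLocus], path: str | os.PathLike,
                   source: str = "mirnet") -> None:
    """miRNA loci as GFF3: one precursor feature with mature/star children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            c = loc.precursor.chrom
            attrs = (f"ID={loc.id};precision={loc.precision:.4f};"
                     f"arm={loc.arm};family={loc.family or 'NA'};"
                     f"conservation={loc.conservation_class or 'NA'}")
            fh.write(_gff_line(c, source, "miRNA_primary_transcript",
                               loc.precursor, attrs) + "\n")
            fh.write(_gff_line(c, source, "miRNA", loc.mature,
                               f"ID={loc.id}.mature;Parent={loc.id};seq={loc.mature_seq}") + "\n")
            fh.write(_gff_line(c, source, "miRNA_star", loc.star,
                               f"ID={loc.id}.star;Parent={loc.id};seq={loc.star_seq}") + "\n")


def read_gff_intervals(path: str | os.PathLike) -> list[tuple[str, str, GenomicInterval, dict]]:
    """Parse a GFF3 file into (feature type, id, interval, attribute dict)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = \
                line.rstrip("\n").split("\t")
            ad = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            iv = GenomicInterval(chrom, int(start) - 1, int(end),
                                 strand if strand in "+-" else "+")
            out.append((ftype, ad.get("ID", ""), iv, ad))
    return out


# ------------------------------------------------------------------ PWM text

def write_pwms(pwms: Iterable[Pwm], path: str | os.PathLike) -> None:
    """JASPAR-style plain text: ``>tf_id`` then one ``A [ ... ]`` row per base."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_id}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.6f}" for v in pwm.matrix[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


def read_pwms(path: str | os.PathLike) -> list[Pwm]:
    pwms = []
    name, rows = None, {}

    def flush():
        if name is not None:
            mat = np.array([rows[b] for b in "ACGT"]).T
            pwms.append(Pwm(name, mat))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], {}
            else:
                base, rest = line.split(None, 1)
                rows[base] = [float(x) for x in
                              rest.replace("[", " ").replace("]", " ").split()]
    flush()
    return pwms


# ---------------------------------------------------------------- TSV tables

def write_density_table(density: Mapping[str, Mapping[int, int]],
                        path: str | os.PathLike) -> None:
    """Degradome 5'-end counts keyed by (transcript, 1-based position)."""
    with open(path, "w") as fh:
        fh.write("transcript\tposition\tcount\n")
        for tx in sorted(density):
            for pos in sorted(density[tx]):
                fh.write(f"{tx}\t{pos}\t{density[tx][pos]}\n")


def read_density_table(path: str | os.PathLike) -> dict[str, dict[int, int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, int]] = {}
    for tx, pos, count in df.itertuples(index=False):
        out.setdefault(tx, {})[int(pos)] = int(count)
    return out


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
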