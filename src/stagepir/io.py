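"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA parsing goes through Biopython, FASTQ through pysam's fastx reader,
and GTF through gffutils; BED6 and the TSV tables are handled with pandas.
Everything written here re-reads round-trip identical (the simulator's
determinism contract depends on it).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import gffutils
import pandas as pd
import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .features import GeneModel, TEFeature

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    with open(path) as fh:
        return {name.split()[0]: seq.upper() for name, seq in SimpleFastaParser(fh)}


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterable[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from a FASTQ (or FASTA) file."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper()


def write_fastq(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(read_id, sequence)`` records with constant quality."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_collapsed_fasta(path: str | os.PathLike) -> list[tuple[str, int]]:
    """Read a collapsed FASTA whose headers end in ``_xN`` copy counts."""
    out = []
    with open(path) as fh:
        for name, seq in SimpleFastaParser(fh):
            token = name.split()[0]
            copies = int(token.rsplit("_x", 1)[1]) if "_x" in token else 1
            out.append((seq.upper(), copies))
    return out


# ---------------------------------------------------------------------------
# BED6

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS
    return df


def write_bed6(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def te_features_to_bed(features: Iterable[TEFeature]) -> pd.DataFrame:
    rows = [(t.chrom, t.start, t.end, t.family, 0, t.strand) for t in features]
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def bed_to_te_features(df: pd.DataFrame) -> list[TEFeature]:
    return [
        TEFeature(r.chrom, int(r.start), int(r.end), r.strand, str(r.name))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# GTF (1-based inclusive on disk, 0-based half-open in memory)


def write_gtf(path: str | os.PathLike, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_biotype "{m.biotype}";'
            )
            fh.write(
                f"{m.chrom}\tstagepir\ttranscript\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tstagepir\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for tx in db.features_of_type("transcript"):
        exons = tuple(
            (e.start - 1, e.end)
            for e in db.children(tx, featuretype="exon", order_by="start")
        )
        models.append(
            GeneModel(
                transcript_id=tx.attributes["transcript_id"][0],
                gene_id=tx.attributes["gene_id"][0],
                chrom=tx.seqid,
                start=tx.start - 1,
                end=tx.end,
                strand=tx.strand,
                biotype=tx.attributes.get("gene_biotype", ["unknown"])[0],
                exons=exons,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


# ---------------------------------------------------------------------------
# TSV tables


def read_fpkm(path: str | os.PathLike) -> pd.DataFrame:
    """FPKM table: transcript_id index x RNA-seq dataset columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fpkm(path: str | os.PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", float_format="%.4f")


def check_chromosomes(genome_chroms: Iterable[str], annotation_chroms: Iterable[str], what: str) -> None:
    """Raise if an annotation references chromosomes absent from the genome."""
    missing = sorted(set(annotation_chroms) - set(genome_chroms))
    if missing:
        raise ValueError(f"{what} references unknown chromosomes: {missing}")
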