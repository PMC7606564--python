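"""Readers and writers for the formats the pipeline consumes and emits.

FASTA/FASTQ go through Biopython; GFF3 and the BED-like read table are
plain tab-separated text.  GFF3 coordinates are converted between the
file's 1-based inclusive convention and the 0-based internal one here and
nowhere else.
"""

from __future__ import annotations

import gzip
import logging
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomeAnnotation, validate_alignments

log = logging.getLogger("nadscape")

_GFF_SOURCE = "nadscape"


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs; qualities are not used downstream."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs with flat Phred-40 qualities."""
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# --------------------------------------------------------------------- GFF3


def read_annotation(path) -> dict[str, GenomeAnnotation]:
    """Parse a GFF3 gene annotation into internal 0-based coordinates.

    Each ``gene`` feature must carry ``ID``, ``gene_class``, ``tls_pos`` and
    ``canonical_tss`` attributes (the latter two 1-based, as the file).
    """
    genes: dict[str, GenomeAnnotation] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                attr = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if kv
                )
                gene_id = attr["ID"]
                tls = int(attr["tls_pos"]) - 1
                tss = int(attr["canonical_tss"]) - 1
                start_i, end_i = int(start) - 1, int(end)  # to 0-based half-open
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed gene record ({exc})")
            if gene_id in genes:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            tes = end_i - 1 if strand == "+" else start_i
            genes[gene_id] = GenomeAnnotation(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                tls_pos=tls,
                canonical_tss=tss,
                tes_pos=tes,
                gene_class=attr.get("gene_class", "mRNA"),
            )
    return genes


def write_annotation(genes: dict[str, GenomeAnnotation], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.values():
            lo = min(g.canonical_tss, g.tes_pos)
            hi = max(g.canonical_tss, g.tes_pos)
            attrs = (
                f"ID={g.gene_id};gene_class={g.gene_class};"
                f"tls_pos={g.tls_pos + 1};canonical_tss={g.canonical_tss + 1}"
            )
            fh.write(
                f"{g.chrom}\t{_GFF_SOURCE}\tgene\t{lo + 1}\t{hi + 1}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------- BED-like reads


def read_alignments(path) -> pd.DataFrame:
    """Read a BED-like read table (chrom, start, end, strand, sample_id).

    Records with an empty or inverted interval are rejected and counted in
    the log rather than raising.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    df = validate_alignments(df)
    bad = df["start"] >= df["end"]
    if bad.any():
        log.warning("read_alignments: rejected %d records with start >= end", int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    tally = df["sample_id"].value_counts().to_dict()
    log.info("read_alignments: %d records, per-sample %s", len(df), tally)
    return df


def write_alignments(df: pd.DataFrame, path) -> None:
    validate_alignments(df).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ result tables


def write_results_table(df: pd.DataFrame, path) -> None:
    """TSV with header, stable column order, >=6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
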