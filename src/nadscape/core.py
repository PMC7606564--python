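"""Shared domain types and coordinate conventions.

All genomic intervals are 0-based half-open internally.  File formats keep
their native conventions (GFF3 is 1-based inclusive, BED-like tables are
0-based half-open); conversion happens exactly once, at I/O time.

"Upstream", "downstream", transcript-leader (TL) length and every windowed
offset are computed in *transcript orientation*, so a single code path
serves both strands: on the minus strand "upstream of position p" means a
numerically larger genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GENE_CLASSES = ("mRNA", "snoRNA", "rRNA", "tRNA", "other")

#: Column order of the BED-like alignment table used throughout.
ALIGNMENT_COLUMNS = ["chrom", "start", "end", "strand", "sample_id"]

#: Column order of the sample sheet.
SAMPLE_COLUMNS = ["sample_id", "strain", "group", "replicate", "library_kind"]


@dataclass(frozen=True)
class GenomeAnnotation:
    """One annotated gene.

    ``canonical_tss`` is the canonical (all-cap) transcription start site,
    ``tls_pos`` the first base of the CDS (translation start, position "0"
    of the 5'-UTR window) and ``tes_pos`` the last transcribed base; all are
    0-based genomic positions of single bases.
    """

    gene_id: str
    chrom: str
    strand: str
    tls_pos: int
    canonical_tss: int
    tes_pos: int
    gene_class: str = "mRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown class {self.gene_class!r}")
        if self.strand == "+":
            ok = self.canonical_tss <= self.tls_pos <= self.tes_pos
        else:
            ok = self.canonical_tss >= self.tls_pos >= self.tes_pos
        if not ok:
            raise ValueError(
                f"{self.gene_id}: TSS/TLS/TES order violates strand {self.strand}"
            )

    # -- transcript-orientation helpers -------------------------------

    @property
    def sign(self) -> int:
        return 1 if self.strand == "+" else -1

    def tl_length(self, pos: int) -> int:
        """5'-UTR (transcript leader) length of a transcript starting at pos."""
        return (self.tls_pos - pos) * self.sign

    def offset_from_tls(self, pos: int) -> int:
        """Signed offset of pos from the translation start, transcript-oriented."""
        return (pos - self.tls_pos) * self.sign

    def offset_from_tss(self, pos: int) -> int:
        return (pos - self.canonical_tss) * self.sign

    def shift(self, pos: int, delta: int) -> int:
        """Move ``delta`` nt downstream (transcript orientation) from pos."""
        return pos + delta * self.sign

    @property
    def utr_length(self) -> int:
        return self.tl_length(self.canonical_tss)

    @property
    def transcript_length(self) -> int:
        return (self.tes_pos - self.canonical_tss) * self.sign + 1


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    strain: str
    group: str  # "S" (+ADPRC) or "N" (-ADPRC) or "T" (transcriptome)
    replicate: int
    library_kind: str = "unfragmented"

    def __post_init__(self) -> None:
        if self.group not in ("S", "N", "T"):
            raise ValueError(f"{self.sample_id}: group must be S, N or T")


def samples_to_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    df = pd.DataFrame([vars(s) for s in samples], columns=SAMPLE_COLUMNS)
    dup = df.duplicated(subset=["strain", "group", "replicate", "library_kind"])
    if dup.any():
        raise ValueError("duplicate (strain, group, replicate, library_kind)")
    return df


@dataclass
class SimTruth:
    """Planted per-gene simulation parameters, used by recovery tests.

    Each gene carries two NAD TSS variants, a distal one (longer TL than
    canonical) and a proximal one (shorter TL); ``distal_mix`` is the
    probability that an NAD-initiated transcript uses the distal variant.
    This makes transcript-leader shifts and the decapping hierarchy
    plantable: an enzyme that removes only one TL class shifts the read-start
    distribution without extinguishing enrichment.
    """

    gene_id: str
    nad_fraction: float
    distal_offset: int  # upstream of canonical TSS, transcript orientation (<0)
    proximal_offset: int  # downstream of canonical TSS (>0)
    distal_mix: float
    has_yaag: bool
    truncation_factor: float
    expression: float = 1.0

    def __post_init__(self) -> None:
        for name in ("nad_fraction", "distal_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.gene_id}: {name}={v} outside [0,1]")


def truth_to_frame(truths: list[SimTruth]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truths])


@dataclass
class CountMatrix:
    """Features x samples integer count table (thin wrapper over a DataFrame)."""

    counts: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and ((arr < 0).any() or (arr != arr.astype(int)).any()):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(int)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[sample_ids].copy())


def validate_alignments(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema of a BED-like alignment table and coerce dtypes."""
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment table missing columns: {missing}")
    df = df[ALIGNMENT_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError("strand column must contain only '+'/'-'")
    return df


def read_five_prime(df: pd.DataFrame) -> pd.Series:
    """Genomic position of each read's 5' base (strand-aware)."""
    plus = df["strand"] == "+"
    return df["start"].where(plus, df["end"] - 1)


def read_three_prime(df: pd.DataFrame) -> pd.Series:
    """Genomic position of each read's 3' base (strand-aware)."""
    plus = df["strand"] == "+"
    return (df["end"] - 1).where(plus, df["start"])
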