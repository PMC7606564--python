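"""Per-read 5'/3' geometry: 2D TSS x TES histograms, full-length fractions
and the S-vs-N truncation contrast.

Coordinates are relative to the canonical TSS in transcript orientation:
``tss`` is the read 5' end minus the canonical TSS, ``tes`` the read 3' end
minus the canonical TSS, so a read spanning the annotated transcript
exactly occupies bin (0, L-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeAnnotation, read_five_prime, read_three_prime

log = logging.getLogger("nadscape")


@dataclass
class GeometryRecord:
    gene_id: str
    group: str
    bins: pd.DataFrame  # columns tss, tes, count
    total_count: int


def build_2d_profile(alignments: pd.DataFrame, annot: GenomeAnnotation,
                     sample_ids: list[str] | None = None,
                     group: str = "") -> GeometryRecord:
    """Unit-bin 2D histogram of (5' start, 3' end) pairs for one gene."""
    df = alignments
    if sample_ids is not None:
        df = df[df["sample_id"].isin(sample_ids)]
    df = df[(df["chrom"] == annot.chrom) & (df["strand"] == annot.strand)]
    five = read_five_prime(df).to_numpy()
    three = read_three_prime(df).to_numpy()
    tss_rel = (five - annot.canonical_tss) * annot.sign
    tes_rel = (three - annot.canonical_tss) * annot.sign
    # a read belongs to the gene when its 5' end is near the leader region
    span = annot.transcript_length
    keep = (tss_rel >= -annot.utr_length - 50) & (tss_rel <= span)
    bins = (pd.DataFrame({"tss": tss_rel[keep], "tes": tes_rel[keep]})
            .value_counts().rename("count").reset_index()
            .sort_values(["tss", "tes"], ignore_index=True))
    return GeometryRecord(annot.gene_id, group, bins, int(bins["count"].sum()))


def full_length_counts(record: GeometryRecord, annot: GenomeAnnotation,
                       tol: int = 3) -> tuple[int, int]:
    """(full-length reads, reads at the dominant TSS) for one gene.

    Reads "with identical TSS" are those starting within +-tol of the
    dominant (modal) TSS; of these, full-length reads also end within
    +-tol of the annotated TES.
    """
    if record.total_count == 0:
        return 0, 0
    bins = record.bins
    by_tss = bins.groupby("tss")["count"].sum()
    dominant = int(by_tss.idxmax())
    at_tss = bins[bins["tss"].sub(dominant).abs() <= tol]
    tes_rel = annot.transcript_length - 1
    full = at_tss[at_tss["tes"].sub(tes_rel).abs() <= tol]["count"].sum()
    return int(full), int(at_tss["count"].sum())


def full_length_fraction(record: GeometryRecord, annot: GenomeAnnotation,
                         tol: int = 3) -> float:
    """Proportion of full-length reads among reads sharing the dominant TSS;
    NaN when the gene has no reads."""
    full, at_tss = full_length_counts(record, annot, tol)
    if at_tss == 0:
        return float("nan")
    return full / at_tss


def pooled_full_length(alignments: pd.DataFrame,
                       annots: dict[str, GenomeAnnotation],
                       gene_ids: list[str], sample_ids: list[str],
                       tol: int = 3) -> tuple[int, int]:
    """(full-length reads, total reads) pooled over a gene set."""
    full = total = 0
    for gid in gene_ids:
        rec = build_2d_profile(alignments, annots[gid], sample_ids)
        f, t = full_length_counts(rec, annots[gid], tol)
        full += f
        total += t
    return full, total


def truncation_contrast(alignments: pd.DataFrame,
                        annots: dict[str, GenomeAnnotation],
                        enriched_ids: list[str], nonenriched_ids: list[str],
                        s_samples: list[str], n_samples: list[str],
                        tol: int = 3) -> dict:
    """Ratio-of-ratios truncation summary.

    R = (S full-length fraction / N full-length fraction) over enriched
    genes, normalized by the same ratio over non-enriched genes; R < 1
    indicates NAD-linked 3'-truncation.
    """
    fs_e, ts_e = pooled_full_length(alignments, annots, enriched_ids, s_samples, tol)
    fn_e, tn_e = pooled_full_length(alignments, annots, enriched_ids, n_samples, tol)
    fs_u, ts_u = pooled_full_length(alignments, annots, nonenriched_ids, s_samples, tol)
    fn_u, tn_u = pooled_full_length(alignments, annots, nonenriched_ids, n_samples, tol)

    def frac(f, t):
        return f / t if t else float("nan")

    ratio_enr = frac(fs_e, ts_e) / frac(fn_e, tn_e)
    if not nonenriched_ids or ts_u == 0 or tn_u == 0:
        log.warning("truncation_contrast: empty non-enriched set, "
                    "reporting unnormalized ratio")
        ratio_non = 1.0
    else:
        ratio_non = frac(fs_u, ts_u) / frac(fn_u, tn_u)
    return {
        "fl_s_enriched": frac(fs_e, ts_e),
        "fl_n_enriched": frac(fn_e, tn_e),
        "fl_s_nonenriched": frac(fs_u, ts_u),
        "fl_n_nonenriched": frac(fn_u, tn_u),
        "ratio_enriched": ratio_enr,
        "ratio_nonenriched": ratio_non,
        "R": ratio_enr / ratio_non,
    }
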