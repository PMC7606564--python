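"""Transcription-start-site analyses.

Read 5' ends are collected over each gene's 5'-UTR plus a 50-nt upstream
extension and expressed as transcript-leader (TL) lengths: the distance
from the read start to the translation start (TLS), so TL = 0 at the TLS
and grows upstream.  On this axis the module provides:

* greedy 18-nt sliding-window TSS cluster detection (densest first);
* the linear-by-linear association trend test between the S/N group label
  and the cluster TL length: with per-read scores X (2 for S, 1 for N) and
  Y (cluster TL length), r = cov(X,Y)/(sd_X sd_Y) on population moments and
  M^2 = (n_obs - 1) r^2 is referred to chi-square with 1 df; genes with
  fewer than ``n_min`` reads (default 30) are untestable;
* "sharp A" TSS calling: the modal read-start position, required to be an
  A with a +1/-1 count ratio above ``sharp_min`` (default 4);
* position frequency matrices of the -10..+10 promoter window with
  per-position information content, for motif recovery (YAAG);
* TSS-shift classification against a canonical reference (distal/proximal
  at >10 nt and FDR < 0.1);
* the transcript-leader length index TLI = (mu_B - mu_A) / W between two
  strains, where mu is the read-count-weighted mean TL length and W the
  scanned window length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GenomeAnnotation, read_five_prime
from .simulate import revcomp
from .stats import bh_fdr

log = logging.getLogger("nadscape")

WINDOW = 18
UPSTREAM = 50
N_MIN = 30
SHARP_MIN = 4.0
SHIFT_MIN = 10
TLI_MIN = 0.1

#: Promoter window labels: 21 positions spanning -10..+10 around the TSS,
#: with the TSS base itself labeled +1 (there is no position 0).
MOTIF_OFFSETS = tuple(range(-10, 0)) + tuple(range(1, 12))


# ------------------------------------------------------------ TL collection


def collect_tl(alignments: pd.DataFrame, annots: dict[str, GenomeAnnotation],
               sample_ids: list[str] | None = None, upstream: int = UPSTREAM,
               ) -> dict[str, np.ndarray]:
    """Per-gene TL lengths of read 5' ends within [TSS - upstream, TLS]."""
    df = alignments
    if sample_ids is not None:
        df = df[df["sample_id"].isin(sample_ids)]
    five = read_five_prime(df).to_numpy()
    keys = pd.DataFrame({"chrom": df["chrom"].to_numpy(),
                         "strand": df["strand"].to_numpy(), "five": five})
    sorted_pos = {k: np.sort(g["five"].to_numpy())
                  for k, g in keys.groupby(["chrom", "strand"], sort=True)}
    out: dict[str, np.ndarray] = {}
    for gid, a in annots.items():
        if a.gene_class in ("rRNA", "tRNA"):
            continue
        max_tl = a.utr_length + upstream
        lo_pos = min(a.tls_pos, a.tls_pos - a.sign * max_tl)
        hi_pos = max(a.tls_pos, a.tls_pos - a.sign * max_tl)
        pos = sorted_pos.get((a.chrom, a.strand))
        if pos is None:
            out[gid] = np.empty(0, dtype=int)
            continue
        i, j = np.searchsorted(pos, [lo_pos, hi_pos + 1])
        tl = (a.tls_pos - pos[i:j]) * a.sign
        out[gid] = tl[(tl >= 0) & (tl <= max_tl)]
    return out


# ---------------------------------------------------------------- clusters


def detect_tss_clusters(tl_s: np.ndarray, tl_n: np.ndarray, max_tl: int,
                        window: int = WINDOW, min_reads: int = 2) -> pd.DataFrame:
    """Greedy TSS cluster detection on the TL-length axis.

    Repeatedly places an 18-nt window at the position holding the most
    pooled (S+N) read starts, records a cluster whose representative is the
    modal position inside the window, removes those reads and repeats until
    no window holds ``min_reads``.  Clusters come back sorted by TL length.
    """
    size = max_tl + 1
    cs = np.bincount(np.asarray(tl_s, dtype=int), minlength=size).astype(float)
    cn = np.bincount(np.asarray(tl_n, dtype=int), minlength=size).astype(float)
    pooled = cs + cn
    win = np.ones(min(window, size))
    rows = []
    while True:
        sums = np.convolve(pooled, win, mode="valid")
        j = int(np.argmax(sums))
        if sums[j] < min_reads:
            break
        span = slice(j, j + len(win))
        rep = j + int(np.argmax(pooled[span]))
        rows.append((rep, int(cs[span].sum()), int(cn[span].sum())))
        pooled[span] = 0.0
        cs[span] = 0.0
        cn[span] = 0.0
    df = pd.DataFrame(rows, columns=["tl", "count_S", "count_N"])
    return df.sort_values("tl", ignore_index=True)


# -------------------------------------------------------------- trend test


@dataclass(frozen=True)
class TrendResult:
    n_obs: int
    r: float
    m2: float
    p: float
    testable: bool


def trend_statistic(row_s, row_n, y) -> tuple[float, float, float]:
    """Weighted linear-by-linear statistic on a 2 x n table.

    Row scores are 2 (top row) and 1 (bottom row), column scores ``y``;
    returns (r, M2, p) with M2 = (n_obs - 1) r^2 on chi-square(1), using
    population moments over the n_obs per-read observations.
    """
    row_s = np.asarray(row_s, dtype=float)
    row_n = np.asarray(row_n, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.concatenate([row_s, row_n])
    x = np.concatenate([np.full(row_s.size, 2.0), np.full(row_n.size, 1.0)])
    yy = np.concatenate([y, y])
    n_obs = w.sum()
    xbar = (w * x).sum() / n_obs
    ybar = (w * yy).sum() / n_obs
    cov = (w * (x - xbar) * (yy - ybar)).sum() / n_obs
    vx = (w * (x - xbar) ** 2).sum() / n_obs
    vy = (w * (yy - ybar) ** 2).sum() / n_obs
    if vx <= 0 or vy <= 0:
        return float("nan"), float("nan"), float("nan")
    r = cov / np.sqrt(vx * vy)
    m2 = (n_obs - 1.0) * r * r
    return float(r), float(m2), float(sps.chi2.sf(m2, df=1))


def linear_trend_test(cluster_table: pd.DataFrame, n_min: int = N_MIN,
                      normalize: bool = True) -> TrendResult:
    """Apply the trend test to a TSS cluster table (tl, count_S, count_N).

    When ``normalize`` is set, the N row is rescaled to the S row's total
    (rounded to integers) before expansion, so that library depth cannot
    masquerade as a trend.  Genes with fewer than ``n_min`` total reads, a
    single cluster, or an empty row are flagged untestable.
    """
    s = cluster_table["count_S"].to_numpy(dtype=float)
    n = cluster_table["count_N"].to_numpy(dtype=float)
    y = cluster_table["tl"].to_numpy(dtype=float)
    if normalize and n.sum() > 0 and s.sum() > 0:
        n = np.rint(n * s.sum() / n.sum())
    n_obs = int(s.sum() + n.sum())
    if (len(y) < 2 or n_obs < n_min or s.sum() == 0 or n.sum() == 0
            or np.unique(y[(s + n) > 0]).size < 2):
        return TrendResult(n_obs, float("nan"), float("nan"), float("nan"), False)
    r, m2, p = trend_statistic(s, n, y)
    if np.isnan(r):
        return TrendResult(n_obs, float("nan"), float("nan"), float("nan"), False)
    return TrendResult(n_obs, r, m2, p, True)


def trend_table(alignments: pd.DataFrame, annots: dict[str, GenomeAnnotation],
                s_samples: list[str], n_samples: list[str],
                upstream: int = UPSTREAM, window: int = WINDOW,
                min_reads: int = 2, n_min: int = N_MIN) -> pd.DataFrame:
    """Run cluster detection + trend test for every gene; BH FDR across the
    testable ones."""
    tls_s = collect_tl(alignments, annots, s_samples, upstream)
    tls_n = collect_tl(alignments, annots, n_samples, upstream)
    rows = []
    for gid, a in annots.items():
        if a.gene_class in ("rRNA", "tRNA"):
            continue
        max_tl = a.utr_length + upstream
        clusters = detect_tss_clusters(tls_s[gid], tls_n[gid], max_tl,
                                       window, min_reads)
        res = linear_trend_test(clusters, n_min=n_min)
        rows.append((gid, len(clusters), res.n_obs, res.r, res.m2, res.p,
                     res.testable))
    df = pd.DataFrame(rows, columns=["gene_id", "n_clusters", "n_obs", "r",
                                     "m2", "p", "testable"])
    df["fdr"] = np.nan
    mask = df["testable"].to_numpy()
    if mask.any():
        df.loc[mask, "fdr"] = bh_fdr(df.loc[mask, "p"].to_numpy())
    return df


# ----------------------------------------------------------------- sharp A


def call_sharp_a(alignments: pd.DataFrame, annots: dict[str, GenomeAnnotation],
                 genome: dict[str, str], sample_ids: list[str] | None = None,
                 upstream: int = UPSTREAM, min_reads: int = 5,
                 sharp_min: float = SHARP_MIN) -> pd.DataFrame:
    """Call the modal read-start TSS per gene and its sharp-A status.

    The sharp value is the read-start count at the TSS (+1) over the count
    at the -1 position (floored at 1); among equally abundant modal
    positions the one with the larger count at its +2 position wins.
    """
    tls = collect_tl(alignments, annots, sample_ids, upstream)
    rows = []
    for gid, a in annots.items():
        if a.gene_class in ("rRNA", "tRNA"):
            continue
        tl = tls[gid]
        if tl.size < min_reads:
            continue
        counts = np.bincount(tl, minlength=a.utr_length + upstream + 2)
        top = counts.max()
        cand = np.flatnonzero(counts == top)
        # +2 position = one base downstream = TL length - 1
        nxt = [counts[c - 1] if c >= 1 else 0 for c in cand]
        order = sorted(range(len(cand)), key=lambda i: (-nxt[i], cand[i]))
        tl_mode = int(cand[order[0]])
        pos = a.tls_pos - a.sign * tl_mode
        base = genome[a.chrom][pos]
        if a.strand == "-":
            base = revcomp(base)
        upstream_count = counts[tl_mode + 1] if tl_mode + 1 < counts.size else 0
        sharp = top / max(upstream_count, 1)
        rows.append((gid, pos, tl_mode, base, float(sharp),
                     bool(base == "A" and sharp > sharp_min), int(tl.size)))
    return pd.DataFrame(rows, columns=["gene_id", "tss_pos", "tl", "base",
                                       "sharp_value", "is_sharp_a", "n_reads"])


# ------------------------------------------------------------ promoter PFM


@dataclass
class PromoterMatrix:
    pfm: pd.DataFrame  # rows A,C,G,T; columns = MOTIF_OFFSETS
    ic: pd.Series  # information content per position, bits
    n_sites: int

    def consensus(self, ic_min: float = 0.5) -> str:
        iupac = {frozenset("CT"): "Y", frozenset("AG"): "R",
                 frozenset("AT"): "W", frozenset("CG"): "S",
                 frozenset("GT"): "K", frozenset("AC"): "M"}
        out = []
        for col in self.pfm.columns:
            if self.ic[col] <= ic_min:
                out.append("n")
                continue
            freqs = self.pfm[col].sort_values(ascending=False)
            if freqs.iloc[0] >= 0.6:
                out.append(freqs.index[0])
            elif freqs.iloc[0] + freqs.iloc[1] >= 0.75:
                out.append(iupac.get(frozenset(freqs.index[:2]), "n"))
            else:
                out.append("n")
        return "".join(out)


def promoter_matrix(tss_calls: pd.DataFrame,
                    annots: dict[str, GenomeAnnotation],
                    genome: dict[str, str],
                    pseudocount: float = 0.25) -> PromoterMatrix:
    """Position frequency matrix of the -10..+10 window around called TSSs,
    in transcript orientation, with per-position information content."""
    windows = []
    for row in tss_calls.itertuples():
        a = annots[row.gene_id]
        chrom = genome[a.chrom]
        lo, hi = row.tss_pos - 10, row.tss_pos + 11
        if lo < 0 or hi > len(chrom):
            log.info("promoter_matrix: %s window off contig, skipped", row.gene_id)
            continue
        seq = chrom[lo:hi]
        windows.append(seq if a.strand == "+" else revcomp(seq))
    counts = np.full((4, len(MOTIF_OFFSETS)), pseudocount)
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in windows:
        for j, b in enumerate(seq):
            if b in index:
                counts[index[b], j] += 1.0
    pfm = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(pfm * np.log2(pfm)).sum(axis=0)
    pfm_df = pd.DataFrame(pfm, index=["A", "C", "G", "T"], columns=MOTIF_OFFSETS)
    ic = pd.Series(2.0 - ent, index=MOTIF_OFFSETS, name="ic")
    return PromoterMatrix(pfm_df, ic, len(windows))


def select_tss_calls(calls: pd.DataFrame, enr: pd.DataFrame, k: int = 25,
                     selection: str = "topK_enriched",
                     fc_down: float = 0.707, fc_up: float = 1.414) -> pd.DataFrame:
    """Pick promoter-matrix input genes: the top-k most enriched sharp-A
    calls, or the k most abundant non-enriched (background) ones."""
    merged = calls.merge(enr, left_on="gene_id", right_on="feature_id")
    sharp = merged[merged["is_sharp_a"]]
    if len(sharp) < k:
        log.info("select_tss_calls: only %d sharp-A genes, using all calls",
                 len(sharp))
        sharp = merged
    if selection == "topK_enriched":
        pool = sharp[sharp["verdict"] == "enriched"]
        if len(pool) < k:
            pool = sharp
        return pool.sort_values(["fc", "gene_id"], ascending=[False, True]).head(k)
    if selection == "background":
        pool = sharp[(sharp["fc"] >= fc_down) & (sharp["fc"] <= fc_up)]
        return pool.sort_values(["nbm", "gene_id"], ascending=[False, True]).head(k)
    raise ValueError(f"unknown selection {selection!r}")


# --------------------------------------------------------------- TSS shift


def tss_shift_table(tl_s: dict[str, np.ndarray],
                    reference: dict[str, np.ndarray | float],
                    shift_min: float = SHIFT_MIN, fdr_max: float = 0.1,
                    min_reads: int = 10) -> pd.DataFrame:
    """Per-gene TL-length shift of the S group against a reference.

    The reference is either an array of reference TL lengths (e.g. N-group
    starts as the all-cap proxy) tested by a two-sided rank-sum, or a point
    canonical TL length tested by a two-sided sign test.  Delta is the
    difference of modal TL lengths; distal means a longer leader.
    """
    rows = []
    for gid, s_vals in tl_s.items():
        if gid not in reference:
            continue
        ref = reference[gid]
        if s_vals.size < min_reads:
            continue
        mode_s = _modal(s_vals)
        if np.isscalar(ref):
            ref_tl = float(ref)
            diff = s_vals - ref_tl
            nz = diff[diff != 0]
            if nz.size == 0:
                p = 1.0
            else:
                p = sps.binomtest(int((nz > 0).sum()), nz.size, 0.5).pvalue
        else:
            ref = np.asarray(ref)
            if ref.size < min_reads:
                continue
            ref_tl = _modal(ref)
            if s_vals.min() == s_vals.max() == ref.min() == ref.max():
                p = 1.0
            else:
                p = sps.mannwhitneyu(s_vals, ref, alternative="two-sided").pvalue
        rows.append((gid, float(mode_s), float(ref_tl),
                     float(mode_s - ref_tl), float(p)))
    df = pd.DataFrame(rows, columns=["gene_id", "tl_s", "tl_ref", "delta", "p"])
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df["direction"] = np.where(
            (df["delta"] > shift_min) & (df["fdr"] < fdr_max), "distal",
            np.where((df["delta"] < -shift_min) & (df["fdr"] < fdr_max),
                     "proximal", "none"))
    else:
        df["fdr"] = []
        df["direction"] = []
    return df


def _modal(values: np.ndarray) -> int:
    counts = np.bincount(np.asarray(values, dtype=int))
    return int(np.argmax(counts))


# --------------------------------------------------------------------- TLI


def compute_tli(tl_a: np.ndarray, tl_b: np.ndarray, window_length: int,
                window: int = WINDOW, min_reads: int = 2,
                n_min: int = N_MIN) -> tuple[float, TrendResult]:
    """Transcript-leader length index of strain B relative to strain A.

    TLI = (mu_B - mu_A) / W with mu the mean TL length of each strain's
    S-group read starts and W the scanned window length; positive TLI means
    B initiates at more distal (longer-leader) positions.  Significance is
    the trend test on the B-vs-A cluster table (mutant row weighted 2).
    """
    if tl_a.size == 0 or tl_b.size == 0:
        return float("nan"), TrendResult(0, np.nan, np.nan, np.nan, False)
    tli = (float(tl_b.mean()) - float(tl_a.mean())) / window_length
    clusters = detect_tss_clusters(tl_b, tl_a, window_length, window, min_reads)
    res = linear_trend_test(clusters, n_min=n_min)
    if min(tl_a.size, tl_b.size) < n_min:
        res = TrendResult(res.n_obs, res.r, res.m2, res.p, False)
    return tli, res


def tli_table(alignments_a: pd.DataFrame, alignments_b: pd.DataFrame,
              annots: dict[str, GenomeAnnotation],
              samples_a: list[str] | None = None,
              samples_b: list[str] | None = None,
              upstream: int = UPSTREAM, tli_min: float = TLI_MIN,
              fdr_max: float = 0.1, n_min: int = N_MIN) -> pd.DataFrame:
    """Per-gene TLI between two strains' S-group read starts, with BH FDR
    and distal/proximal direction calls."""
    tls_a = collect_tl(alignments_a, annots, samples_a, upstream)
    tls_b = collect_tl(alignments_b, annots, samples_b, upstream)
    rows = []
    for gid, a in annots.items():
        if a.gene_class in ("rRNA", "tRNA"):
            continue
        W = a.utr_length + upstream
        tli, res = compute_tli(tls_a[gid], tls_b[gid], W, n_min=n_min)
        rows.append((gid, tli, tls_a[gid].size, tls_b[gid].size,
                     res.p, res.testable))
    df = pd.DataFrame(rows, columns=["gene_id", "tli", "n_a", "n_b", "p",
                                     "testable"])
    df["fdr"] = np.nan
    mask = df["testable"].to_numpy()
    if mask.any():
        df.loc[mask, "fdr"] = bh_fdr(df.loc[mask, "p"].to_numpy())
    df["direction"] = np.where(
        (df["tli"] > tli_min) & (df["fdr"] < fdr_max), "distal",
        np.where((df["tli"] < -tli_min) & (df["fdr"] < fdr_max),
                 "proximal", "none"))
    return df
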