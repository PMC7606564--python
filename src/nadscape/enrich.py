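"""S-vs-N enrichment statistics, TPM, NAD-modification ratios and small-RNA
cluster assembly.

The enrichment test is a negative-binomial Wald test on the log fold change
between +ADPRC (S) and -ADPRC (N) libraries: counts are normalized by
median-of-ratios size factors, the NB dispersion is estimated per feature by
method of moments (floored), and the Wald statistic compares the log ratio
of group means against its delta-method standard error.  Verdicts apply the
published thresholds (FC > 1.414, NBM > 1, p < 0.05 for enrichment;
FC < 0.707 for depletion), with strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

log = logging.getLogger("nadscape")

FC_UP = 1.414
FC_DOWN = 0.707
NBM_MIN = 1.0
ALPHA = 0.05


def size_factors(counts: pd.DataFrame,
                 control_features: pd.Index | list | None = None) -> pd.Series:
    """Median-of-ratios normalization to the geometric-mean pseudo-reference.

    When ``control_features`` is given, the median is taken over those
    features only (e.g. features not differentially captured), which keeps
    the factors unbiased when a large fraction of features is enriched.
    """
    sub = counts if control_features is None else counts.loc[control_features]
    arr = sub.to_numpy(dtype=float)
    expressed = (arr > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "add a pseudo-count or filter samples")
    logc = np.log(arr[expressed])
    ref = logc.mean(axis=1)
    sf = np.exp(np.median(logc - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _moments_dispersion(norm: np.ndarray, groups: list[np.ndarray],
                        floor: float) -> np.ndarray:
    """Method-of-moments NB dispersion per feature, pooled over groups."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        x = norm[:, idx]
        mu = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        ok = mu > 0
        num[ok] += var[ok] - mu[ok]
        den[ok] += mu[ok] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), floor)
    return np.clip(alpha, floor, 20.0)


def enrichment_test(counts: pd.DataFrame, meta: pd.DataFrame,
                    strain: str | None = None,
                    group_a: str = "S", group_b: str = "N",
                    library_kind: str | None = None,
                    fc_up: float = FC_UP, fc_down: float = FC_DOWN,
                    nbm_min: float = NBM_MIN, alpha: float = ALPHA,
                    disp_floor: float = 0.01) -> pd.DataFrame:
    """Per-feature S-vs-N enrichment records.

    ``meta`` is a sample sheet (sample_id, strain, group, replicate,
    library_kind); the same routine serves transcriptome differential
    expression by passing two strains' sample sets via ``group_a``/``group_b``
    columns prepared by the caller.
    """
    sel = meta.copy()
    if strain is not None:
        sel = sel[sel["strain"] == strain]
    if library_kind is not None:
        sel = sel[sel["library_kind"] == library_kind]
    a_ids = sel.loc[sel["group"] == group_a, "sample_id"].tolist()
    b_ids = sel.loc[sel["group"] == group_b, "sample_id"].tolist()
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError(
            f"need >=2 replicates per group, got {len(a_ids)} {group_a} / "
            f"{len(b_ids)} {group_b}")
    cols = a_ids + b_ids
    sub = counts[cols]
    na, nb = len(a_ids), len(b_ids)
    ia, ib = np.arange(na), np.arange(na, na + nb)
    allzero = sub.to_numpy().sum(axis=1) == 0

    def one_pass(sf: pd.Series):
        norm = sub.to_numpy(dtype=float) / sf.to_numpy()
        nbm = norm.mean(axis=1)
        m_a = norm[:, ia].mean(axis=1)
        m_b = norm[:, ib].mean(axis=1)
        fc = (m_a + 0.5) / (m_b + 0.5)
        disp = _moments_dispersion(norm, [ia, ib], disp_floor)
        var_ln = ((1.0 / (m_a + 0.5) + disp) / na
                  + (1.0 / (m_b + 0.5) + disp) / nb)
        z = np.log(fc) / np.sqrt(var_ln)
        p = 2.0 * sps.norm.sf(np.abs(z))
        p[allzero] = 1.0
        return nbm, fc, p

    # two-pass normalization: the second pass re-estimates size factors on
    # features not flagged as enriched in the first, so the factors stay
    # unbiased even when a sizeable fraction of features is truly captured
    # (capture enrichment is one-sided; apparent depletion of unflagged
    # features is usually the normalization artifact being corrected here)
    nbm, fc, p = one_pass(size_factors(sub))
    flagged = (fc > fc_up) & (p < alpha)
    controls = sub.index[~flagged]
    if 0 < flagged.sum() < len(sub):
        try:
            nbm, fc, p = one_pass(size_factors(sub, controls))
        except ValueError:
            pass  # keep first-pass results if controls are unusable
    fdr = bh_fdr(p)

    verdict = np.where(
        (fc > fc_up) & (nbm > nbm_min) & (p < alpha), "enriched",
        np.where((fc < fc_down) & (nbm > nbm_min) & (p < alpha),
                 "depleted", "ns"))
    verdict[allzero] = "ns"
    return pd.DataFrame({
        "feature_id": sub.index,
        "nbm": nbm,
        "fc": fc,
        "log2fc": np.log2(fc),
        "p_value": p,
        "fdr": fdr,
        "verdict": verdict,
    }).reset_index(drop=True)


# ------------------------------------------------------------------- TPM


def tpm(counts: pd.DataFrame, feature_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per kilobase million; each sample column sums to 1e6."""
    lengths = feature_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    rpk = counts.div(lengths / 1e3, axis=0)
    return rpk.div(rpk.sum(axis=0), axis=1) * 1e6


def nad_ratio_tpm(k: float, tpm_nad: pd.Series, tpm_all: pd.Series) -> pd.DataFrame:
    """Relative per-feature NAD-modification ratio, k * TPM_NAD / TPM_all.

    ``k`` is the externally measured total NAD-RNA amount (e.g. from
    UPLC-MS), supplied as a scalar on a relative scale.  Features with zero
    transcriptome TPM are omitted.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    common = tpm_nad.index.intersection(tpm_all.index)
    nad = tpm_nad.reindex(common)
    allc = tpm_all.reindex(common)
    zero = allc == 0
    if zero.any():
        log.info("nad_ratio_tpm: omitting %d features with zero total TPM",
                 int(zero.sum()))
    nad, allc = nad[~zero], allc[~zero]
    ratio = np.clip(k * nad / allc, 0.0, 1.0)
    return pd.DataFrame({"feature_id": ratio.index, "ratio": ratio.to_numpy(),
                         "method": "tpm_integration"}).reset_index(drop=True)


def nad_ratio_qpcr(s_signal: float, bg_signal: float, noncap_signal: float) -> float:
    """qRT-PCR modification ratio:
    (S - background) / (S + other-cap), clipped to [0, 1]; NaN when the
    denominator is zero."""
    if min(s_signal, bg_signal, noncap_signal) < 0:
        raise ValueError("signals must be non-negative")
    denom = s_signal + noncap_signal
    if denom == 0:
        return float("nan")
    return float(np.clip((s_signal - bg_signal) / denom, 0.0, 1.0))


# ----------------------------------------------------------- small RNAs


def _identity(a: str, b: str, max_offset: int = 3) -> float:
    """Ungapped identity over the shorter read at the best offset in
    [-max_offset, max_offset]."""
    short = min(len(a), len(b))
    best = 0
    for off in range(-max_offset, max_offset + 1):
        m = 0
        for i in range(short):
            j = i + off
            if 0 <= j < len(b) and i < len(a) and a[i] == b[j]:
                m += 1
        best = max(best, m)
    return best / short


def cluster_small_rnas(reads: pd.DataFrame, min_identity: float = 0.6,
                       max_copy_ratio: float = 50.0,
                       fc_up: float = FC_UP) -> pd.DataFrame:
    """Assemble small-RNA clusters by greedy seeding.

    ``reads`` needs columns sequence, strand, copies_S, copies_N.  Identical
    (sequence, strand) rows are merged first; reads then seed clusters in
    descending total-copy order and join the first cluster whose seed they
    match at >= ``min_identity`` on the same strand while keeping the
    max/min member copy ratio <= ``max_copy_ratio``.

    Cluster enrichment is total S copies over total N copies; clusters with
    zero N copies are flagged ``n_zero`` rather than assigned a number.
    """
    agg = (reads.groupby(["sequence", "strand"], as_index=False)
           [["copies_S", "copies_N"]].sum())
    agg["total"] = agg["copies_S"] + agg["copies_N"]
    agg = agg.sort_values(["total", "sequence"],
                          ascending=[False, True]).reset_index(drop=True)
    clusters: list[dict] = []
    for row in agg.itertuples():
        placed = False
        for cl in clusters:
            if cl["strand"] != row.strand:
                continue
            if _identity(row.sequence, cl["seed"]) < min_identity:
                continue
            hi = max(cl["max_copy"], row.total)
            lo = min(cl["min_copy"], row.total)
            if lo > 0 and hi / lo > max_copy_ratio:
                continue
            cl["members"] += 1
            cl["copies_S"] += row.copies_S
            cl["copies_N"] += row.copies_N
            cl["max_copy"], cl["min_copy"] = hi, lo
            placed = True
            break
        if not placed:
            clusters.append({
                "seed": row.sequence, "strand": row.strand, "members": 1,
                "copies_S": row.copies_S, "copies_N": row.copies_N,
                "max_copy": row.total, "min_copy": row.total,
            })
    rows = []
    for i, cl in enumerate(clusters):
        if cl["copies_N"] > 0:
            enr = cl["copies_S"] / cl["copies_N"]
            flag = "enriched" if enr > fc_up else "ns"
        else:
            enr = float("inf")
            flag = "n_zero"
        rows.append((f"c{i + 1:04d}", cl["seed"], cl["strand"], cl["members"],
                     cl["copies_S"], cl["copies_N"], enr, flag))
    return pd.DataFrame(rows, columns=[
        "cluster_id", "seed_sequence", "strand", "n_members",
        "copies_S", "copies_N", "enrichment", "status"])
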