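"""Seeded validation benchmarks: every stage of the pipeline measured
against planted truth or an independent oracle.

Each function runs a self-contained experiment at a fixed design (sample
sizes, planted effect sizes and noise levels are part of the experiment
definition) and returns the measured quantities.  The test suite asserts on
these numbers; the acceptance script reports them.
"""

from __future__ import annotations

import re
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import samples_to_frame
from .enrich import enrichment_test, nad_ratio_tpm, tpm
from .geometry import truncation_contrast
from .lattice import run_lattice
from .readproc import count_features, trim_read
from .simulate import (SimConfig, add_adapters, effective_nad_fraction,
                       make_genome, simulate_reads)
from .tss import (call_sharp_a, collect_tl, detect_tss_clusters,
                  linear_trend_test, promoter_matrix, select_tss_calls,
                  trend_statistic, tss_shift_table)

TRIPLE_KO = "dxo1d_npy1d_rai1d"


def _rng(seed: int, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng((int(seed) + offset) % (2**31 - 1))


# ----------------------------------------------------------- trend test


def trend_oracle_max_diff(seed: int, n_tables: int = 200) -> dict:
    """Largest deviation between the grouped trend statistic and its
    per-observation expansion (Pearson r on expanded reads)."""
    rng = _rng(seed, 1)
    worst = 0.0
    done = 0
    while done < n_tables:
        n = int(rng.integers(2, 7))
        y = np.sort(rng.choice(np.arange(1, 150), size=n, replace=False))
        s = rng.integers(0, 25, size=n)
        t = rng.integers(0, 25, size=n)
        x = np.concatenate([np.repeat(2, s.sum()), np.repeat(1, t.sum())])
        yy = np.concatenate([np.repeat(y, s), np.repeat(y, t)])
        if s.sum() == 0 or t.sum() == 0 or np.std(x) == 0 or np.std(yy) == 0:
            continue
        r, m2, _ = trend_statistic(s, t, y.astype(float))
        r_o = np.corrcoef(x, yy)[0, 1]
        worst = max(worst, abs(r - r_o), abs(m2 - (x.size - 1) * r_o**2))
        done += 1
    return {"max_abs_diff": worst, "n": n_tables}


def trend_null_calibration(seed: int, n_genes: int = 2000,
                           reads: int = 100) -> dict:
    """Null genes: S and N read starts drawn from the same multi-TSS
    distribution (modes separated beyond the 18-nt merging window)."""
    rng = _rng(seed, 2)
    ps = []
    while len(ps) < n_genes:
        max_tl = 120
        k = int(rng.integers(2, 5))
        while True:
            centers = np.sort(rng.choice(np.arange(5, 115), size=k,
                                         replace=False))
            if np.diff(centers).min() >= 25:
                break
        w = rng.dirichlet(np.ones(k))

        def draw(m):
            c = centers[rng.choice(k, size=m, p=w)]
            return np.clip(c + rng.integers(-2, 3, size=m), 0, max_tl)

        clusters = detect_tss_clusters(draw(reads), draw(reads), max_tl)
        res = linear_trend_test(clusters)
        if res.testable:
            ps.append(res.p)
    ps = np.asarray(ps)
    return {"ks": float(sps.kstest(ps, "uniform").statistic),
            "type1": float((ps < 0.05).mean()), "n": n_genes}


# ------------------------------------------------------------ TSS shift


def shift_recovery(seed: int, n_genes: int = 200) -> dict:
    """Planted +-30 nt TSS shifts at ~100 captured S reads per gene,
    classified against the canonical TSS as point reference."""
    rng = _rng(seed, 3)
    cfg = SimConfig(n_genes=n_genes, null_fraction=0.0,
                    nad_fraction=(0.25, 0.35), utr_length=(40, 90),
                    distal_offset=(30, 30), proximal_offset=(30, 30),
                    within_gene_mix=False, distal_mix=0.5,
                    reads_per_gene=200, small_rna_fraction=0.0)
    genome, annots, truths = make_genome(cfg, rng)
    aln, _s, samples, _m = simulate_reads(genome, annots, truths, cfg,
                                          TRIPLE_KO, rng)
    meta = samples_to_frame(samples)
    s_ids = meta.loc[meta["group"] == "S", "sample_id"].tolist()
    tls = collect_tl(aln, annots, s_ids)
    ref = {g: float(a.utr_length) for g, a in annots.items()}
    table = tss_shift_table(tls, ref).set_index("gene_id")
    truth_dir = {t.gene_id: ("distal" if t.distal_mix == 1.0 else "proximal")
                 for t in truths}
    correct = sum(g in table.index and table.at[g, "direction"] == d
                  for g, d in truth_dir.items())
    return {"detection_rate": correct / len(truth_dir), "n": len(truth_dir)}


# ----------------------------------------------------------------- motif


def motif_recovery(seed: int, n_genes: int = 100) -> dict:
    """Promoter-matrix recovery of the planted YAAG core from the top-25
    most enriched sharp-A genes, with and without planting."""
    out = {}
    for tag, yaag in (("yaag", 1.0), ("null", 0.0)):
        rng = _rng(seed, 4 if yaag else 5)
        cfg = SimConfig(n_genes=n_genes, null_fraction=0.5,
                        nad_fraction=(0.2, 0.3), yaag_fraction=yaag,
                        reads_per_gene=600, small_rna_fraction=0.0)
        genome, annots, truths = make_genome(cfg, rng)
        aln, _s, samples, _m = simulate_reads(genome, annots, truths, cfg,
                                              TRIPLE_KO, rng)
        meta = samples_to_frame(samples)
        counts, _ = count_features(aln, annots)
        enr = enrichment_test(counts, meta, strain=TRIPLE_KO)
        s_ids = meta.loc[meta["group"] == "S", "sample_id"].tolist()
        calls = call_sharp_a(aln, annots, genome, s_ids)
        top = select_tss_calls(calls, enr, k=25)
        pm = promoter_matrix(top, annots, genome)
        out[f"ic_plus2_{tag}"] = float(pm.ic[2])
        out[f"ic_plus3_{tag}"] = float(pm.ic[3])
        if yaag:
            cons = pm.consensus()
            out["consensus_core"] = cons[9:13]  # positions -1..+3
    out["n"] = n_genes
    return out


# ------------------------------------------------------------ enrichment


def enrichment_recovery(seed: int, n_sims: int = 8,
                        n_genes: int = 300) -> dict:
    """Fraction of genes with planted effective NAD fraction >= 0.02 called
    enriched at the standard thresholds, and the false-positive rate among
    null genes, pooled over several default-condition simulations."""
    hits = tot = fp = fp_tot = 0
    for i in range(n_sims):
        rng = _rng(seed, 10 + i)
        cfg = SimConfig(n_genes=n_genes, small_rna_fraction=0.0)
        genome, annots, truths = make_genome(cfg, rng)
        aln, _s, samples, _m = simulate_reads(genome, annots, truths, cfg,
                                              TRIPLE_KO, rng)
        counts, _ = count_features(aln, annots)
        enr = enrichment_test(counts, samples_to_frame(samples),
                              strain=TRIPLE_KO).set_index("feature_id")
        rho = np.array([effective_nad_fraction(t, ()) for t in truths])
        called = enr.loc[[t.gene_id for t in truths],
                         "verdict"].to_numpy() == "enriched"
        hi, null = rho >= 0.02, rho == 0
        hits += int(called[hi].sum())
        tot += int(hi.sum())
        fp += int(called[null].sum())
        fp_tot += int(null.sum())
    return {"power": hits / tot, "false_positive_rate": fp / fp_tot,
            "n": tot, "n_null": fp_tot}


# ----------------------------------------------------------------- ratio


def ratio_recovery(seed: int, n_genes: int = 300) -> dict:
    """Spearman correlation between the TPM-integration modification-ratio
    estimate and the planted effective NAD fraction, over a mixed population
    of capped and uncapped genes."""
    rng = _rng(seed, 20)
    cfg = SimConfig(n_genes=n_genes, null_fraction=0.5,
                    small_rna_fraction=0.0)
    genome, annots, truths = make_genome(cfg, rng)
    aln, _s, samples, _m = simulate_reads(genome, annots, truths, cfg,
                                          TRIPLE_KO, rng,
                                          groups=("S", "T"))
    meta = samples_to_frame(samples)
    counts, _ = count_features(aln, annots)
    lengths = pd.Series({g: a.transcript_length for g, a in annots.items()})
    t = tpm(counts, lengths)
    s_ids = meta.loc[meta["group"] == "S", "sample_id"].tolist()
    t_ids = meta.loc[meta["group"] == "T", "sample_id"].tolist()
    ratios = nad_ratio_tpm(0.03, t[s_ids].mean(axis=1),
                           t[t_ids].mean(axis=1)).set_index("feature_id")
    rho = pd.Series({x.gene_id: effective_nad_fraction(x, ()) for x in truths})
    r = sps.spearmanr(ratios["ratio"], rho.loc[ratios.index]).statistic
    return {"spearman": float(r), "n": len(ratios)}


# ------------------------------------------------------------ truncation


def _truncation_r(seed: int, factor: float) -> float:
    rng = _rng(seed, 30)
    cfg = SimConfig(n_genes=60, null_fraction=0.7, nad_fraction=(0.15, 0.25),
                    reads_per_gene=400, truncation_factor=factor,
                    small_rna_fraction=0.0)
    genome, annots, truths = make_genome(cfg, rng)
    aln, _s, samples, _m = simulate_reads(genome, annots, truths, cfg,
                                          TRIPLE_KO, rng)
    meta = samples_to_frame(samples)
    counts, _ = count_features(aln, annots)
    enr = enrichment_test(counts, meta, strain=TRIPLE_KO)
    s_ids = meta.loc[meta["group"] == "S", "sample_id"].tolist()
    n_ids = meta.loc[meta["group"] == "N", "sample_id"].tolist()
    return truncation_contrast(
        aln, annots,
        enr.loc[enr["verdict"] == "enriched", "feature_id"].tolist(),
        enr.loc[enr["verdict"] == "ns", "feature_id"].tolist(),
        s_ids, n_ids)["R"]


def truncation_benchmark(seed: int, n_seeds: int = 50) -> dict:
    """Ratio-of-ratios R under planted 3x NAD truncation vs no bias."""
    r_bias = np.array([_truncation_r(seed + 7919 * i, 3.0)
                       for i in range(n_seeds)])
    r_null = np.array([_truncation_r(seed + 104729 * (i + 1), 1.0)
                       for i in range(n_seeds)])
    return {
        "frac_R_below_1_biased": float((r_bias < 1).mean()),
        "mean_R_biased": float(np.nanmean(r_bias)),
        "frac_R_in_band_null": float(((r_null > 0.9) & (r_null < 1.1)).mean()),
        "mean_R_null": float(np.nanmean(r_null)),
        "n": n_seeds,
    }


# ------------------------------------------------------------- hierarchy


def hierarchy_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of lattice simulations in which the top-scoring path starts
    with Rai1 (the planted TL-selective, first-acting enzyme)."""
    wins = 0
    for i in range(n_seeds):
        cfg = SimConfig(n_genes=80, null_fraction=0.6,
                        nad_fraction=(0.2, 0.3), utr_length=(45, 70),
                        distal_offset=(35, 45), proximal_offset=(20, 25),
                        distal_mix=0.5, reads_per_gene=400,
                        small_rna_fraction=0.0)
        paths = run_lattice(cfg, _rng(seed, 40 + i))
        top = paths.sort_values(["n_resolved", "n_shifted"],
                                ascending=False).iloc[0]
        wins += top["first_enzyme"] == "rai1"
    return {"rai1_first_fraction": wins / n_seeds, "n": n_seeds}


# ---------------------------------------------------------------- trimming


def trim_roundtrip(seed: int, n_reads: int = 10000) -> dict:
    """trim(add_adapters(x)) = x for unambiguous inserts >= 12 nt, plus the
    exact 12/17/18-nt classification boundaries."""
    rng = _rng(seed, 50)
    bases = np.array(list("ACGT"))
    inserts = []
    while len(inserts) < n_reads:
        n = int(rng.integers(12, 70))
        ins = "".join(rng.choice(bases, size=n))
        if ins[0] == "G" or re.search(r"C[ACGT]{6}AGATCG", ins):
            continue
        inserts.append(ins)
    raws = add_adapters(inserts, rng)
    ok = sum(trim_read(raw).sequence == ins
             for raw, ins in zip(raws, inserts))
    boundary_ok = all(
        trim_read("GGG" + "A" * L + "C" + "TTTTTT" + "AGATCG").klass == k
        for L, k in ((11, "discarded"), (12, "small"), (17, "small"),
                     (18, "normal")))
    return {"identity_rate": ok / n_reads, "boundaries_exact": boundary_ok,
            "n": n_reads}


# -------------------------------------------------------------- pipeline


def determinism_check(seed: int) -> dict:
    """run-all twice with the same seed: all result tables byte-identical."""
    from .config import RunConfig, run_pipeline

    cfg = RunConfig(seed=seed)
    cfg.sim.n_genes = 40
    cfg.sim.reads_per_gene = 800
    with tempfile.TemporaryDirectory() as tmp:
        d1, d2 = Path(tmp) / "a", Path(tmp) / "b"
        run_pipeline(cfg, d1)
        run_pipeline(cfg, d2)
        names = sorted(p.name for p in d1.iterdir())
        identical = all((d1 / n).read_bytes() == (d2 / n).read_bytes()
                        for n in names)
    return {"identical": identical, "n": len(names)}
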