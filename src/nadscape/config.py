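"""Run configuration and the end-to-end pipeline.

A single global seed fans out to per-stage seeds by stable hashing of the
stage name, so any stage can be re-run in isolation and the whole run is
byte-reproducible.  Every threshold is echoed into the output manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, geometry, io, readproc, tss
from .core import samples_to_frame, truth_to_frame
from .simulate import SimConfig, make_genome, reads_to_fastq, simulate_reads


def stage_seed(seed: int, stage: str) -> int:
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


@dataclass
class Thresholds:
    """All decision thresholds, defaulting to the published cut-offs."""

    fc_up: float = 1.414
    fc_down: float = 0.707
    nbm_min: float = 1.0
    alpha: float = 0.05
    window: int = 18
    upstream: int = 50
    n_min: int = 30
    sharp_min: float = 4.0
    motif_top_k: int = 25
    shift_min: float = 10.0
    tli_min: float = 0.1
    tli_fdr: float = 0.1
    fl_tol: int = 3
    r_min: float = 2.0
    disp_floor: float = 0.01


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    strain: str = "dxo1d_npy1d_rai1d"  # triple knockout: no NAD decapping
    mode: str = "aligned"  # "aligned" or "fastq"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("gene_length", "utr_length", "nad_fraction", "jitter",
                    "distal_offset", "proximal_offset"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        thr_raw = raw.pop("thresholds", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(sim=SimConfig(**sim_raw), thresholds=Thresholds(**thr_raw), **raw)

    def manifest(self) -> dict:
        return {
            "sim": self.sim.manifest(),
            "thresholds": dataclasses.asdict(self.thresholds),
            "strain": self.strain,
            "mode": self.mode,
            "seed": self.seed,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate -> (trim/map) -> count -> enrich -> tss -> motif -> geometry.

    Writes every stage's table under ``outdir`` and returns the manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest = config.manifest()

    # --- simulate ----------------------------------------------------
    genome, annots, truths = make_genome(config.sim, stage_rng(config.seed, "genome"))
    io.write_fasta(genome, out / "genome.fasta")
    io.write_annotation(annots, out / "genes.gff3")
    io.write_results_table(truth_to_frame(truths), out / "truth.tsv")

    aln, small, samples, sim_manifest = simulate_reads(
        genome, annots, truths, config.sim, config.strain,
        stage_rng(config.seed, f"reads:{config.strain}"))
    meta = samples_to_frame(samples)
    io.write_results_table(meta, out / "samples.tsv")
    manifest["simulate"] = sim_manifest

    if config.mode == "fastq":
        fastqs = reads_to_fastq(aln, small, genome, config.sim,
                                stage_rng(config.seed, "fastq"))
        frames, small_rows, tallies = [], [], {}
        for sample_id in sorted(fastqs):
            io.write_fastq(fastqs[sample_id], out / f"reads_{sample_id}.fastq")
            trimmed, tally = readproc.trim_and_classify(fastqs[sample_id])
            normal = [t for t in trimmed if t.klass == "normal"]
            small_reads = [t for t in trimmed if t.klass == "small"]
            mapped, map_tally = readproc.map_reads(
                normal, genome, sample_id, stage_rng(config.seed, f"map:{sample_id}"))
            frames.append(mapped)
            group = "S" if "_S" in sample_id else "N"
            for t in small_reads:
                small_rows.append((t.sequence, "+", "", sample_id, group))
            tallies[sample_id] = {**tally, **map_tally}
        aln = pd.concat(frames, ignore_index=True)
        small = pd.DataFrame(small_rows, columns=["sequence", "strand",
                                                  "gene_id", "sample_id", "group"])
        manifest["readproc"] = tallies
    io.write_alignments(aln[["chrom", "start", "end", "strand", "sample_id"]],
                        out / "alignments.tsv")
    io.write_results_table(small, out / "small_rnas.tsv")

    # --- count + enrichment ------------------------------------------
    counts, excluded = readproc.count_features(aln, annots,
                                               window=(-120, 65))
    counts.rename_axis("feature_id").reset_index().to_csv(
        out / "counts.tsv", sep="\t", index=False)
    io.write_results_table(excluded, out / "excluded_classes.tsv")
    enr = enrich.enrichment_test(
        counts, meta, strain=config.strain,
        fc_up=thr.fc_up, fc_down=thr.fc_down, nbm_min=thr.nbm_min,
        alpha=thr.alpha, disp_floor=thr.disp_floor)
    io.write_results_table(enr, out / "enrichment.tsv")

    s_ids = meta.loc[meta["group"] == "S", "sample_id"].tolist()
    n_ids = meta.loc[meta["group"] == "N", "sample_id"].tolist()

    # --- small-RNA clusters -------------------------------------------
    if len(small):
        agg = (small.assign(copies=1)
               .groupby(["sequence", "strand", "group"])["copies"].sum()
               .unstack("group", fill_value=0).reset_index())
        for col in ("S", "N"):
            if col not in agg:
                agg[col] = 0
        agg = agg.rename(columns={"S": "copies_S", "N": "copies_N"})
        clusters = enrich.cluster_small_rnas(agg, fc_up=thr.fc_up)
    else:
        clusters = pd.DataFrame()
    io.write_results_table(clusters, out / "small_rna_clusters.tsv")

    # --- TSS analyses -------------------------------------------------
    trend = tss.trend_table(aln, annots, s_ids, n_ids, upstream=thr.upstream,
                            window=thr.window, n_min=thr.n_min)
    io.write_results_table(trend, out / "trend.tsv")
    calls = tss.call_sharp_a(aln, annots, genome, s_ids,
                             upstream=thr.upstream, sharp_min=thr.sharp_min)
    io.write_results_table(calls, out / "sharpa.tsv")
    top = tss.select_tss_calls(calls, enr, k=thr.motif_top_k,
                               selection="topK_enriched",
                               fc_down=thr.fc_down, fc_up=thr.fc_up)
    pm = tss.promoter_matrix(top, annots, genome)
    pfm_out = pm.pfm.T.rename_axis("offset").reset_index()
    pfm_out["ic"] = pm.ic.to_numpy()
    io.write_results_table(pfm_out, out / "promoter_pfm.tsv")
    manifest["motif"] = {"n_sites": pm.n_sites, "consensus": pm.consensus()}

    tls_s = tss.collect_tl(aln, annots, s_ids, thr.upstream)
    tls_n = tss.collect_tl(aln, annots, n_ids, thr.upstream)
    shifts = tss.tss_shift_table(tls_s, tls_n, shift_min=thr.shift_min,
                                 fdr_max=thr.tli_fdr)
    io.write_results_table(shifts, out / "tss_shifts.tsv")

    # --- geometry -----------------------------------------------------
    enriched_ids = enr.loc[enr["verdict"] == "enriched", "feature_id"].tolist()
    non_ids = enr.loc[enr["verdict"] == "ns", "feature_id"].tolist()
    contrast = geometry.truncation_contrast(aln, annots, enriched_ids,
                                            non_ids, s_ids, n_ids, thr.fl_tol)
    io.write_results_table(pd.DataFrame([contrast]), out / "truncation_contrast.tsv")
    manifest["geometry"] = contrast
    manifest["n_enriched"] = len(enriched_ids)

    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))}
    manifest["checksums"]["genome.fasta"] = _sha256(out / "genome.fasta")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
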