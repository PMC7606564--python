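"""Synthetic NAD captureSeq data with known planted truth.

The generator emulates the statistical structure the downstream analysis
assumes, without claiming mechanistic realism:

* per-gene NAD-modification fractions drawn from a low range (1-5% by
  default, matching the regime where most transcripts are rarely modified);
* paired +ADPRC ("S") and -ADPRC ("N") libraries, where S captures
  NAD-capped 5'-ends with efficiency ``capture_efficiency`` plus background
  binding ``background_rate``, and N sees background only;
* two NAD TSS variants per gene (a distal one upstream of the canonical TSS
  and a proximal one downstream), with a planted YAAG core motif
  (pyrimidine at -1, A at +1/+2, G at +3) around the NAD TSS for a
  configurable fraction of genes;
* geometric 3'-truncation with a higher per-nucleotide stop probability for
  NAD-capped transcripts;
* strain-specific decapping: each enzyme carries a survival probability per
  TL class {distal, proximal}, and a knockout strain simply deactivates
  the deleted enzymes;
* 12-17 nt small-RNA fragments and spike-in control reads at configured
  rates.

All randomness flows through a single ``numpy.random.Generator``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeAnnotation, SampleMeta, SimTruth

ENZYMES = ("rai1", "dxo1", "npy1")

#: Decapping survival per enzyme per TL class.  Rai1 acts co-transcriptionally
#: in the nucleus and is modeled as TL-selective (it clears distal-TL
#: variants); Dxo1 and Npy1 act downstream without TL selectivity.
DEFAULT_ENZYMES: dict[str, dict[str, float]] = {
    "rai1": {"distal": 0.10, "proximal": 1.00},
    "dxo1": {"distal": 0.60, "proximal": 0.60},
    "npy1": {"distal": 0.30, "proximal": 0.30},
}


def default_strains() -> dict[str, tuple[str, ...]]:
    """All eight knockout combinations, keyed by strain name.

    Strain names list the *deleted* enzymes ("wt" = none deleted); the value
    is the tuple of enzymes still active.
    """
    strains: dict[str, tuple[str, ...]] = {}
    for mask in range(8):
        deleted = sorted(e for i, e in enumerate(ENZYMES) if mask >> i & 1)
        active = tuple(e for e in ENZYMES if e not in deleted)
        name = "_".join(f"{e}d" for e in deleted) if deleted else "wt"
        strains[name] = active
    return strains


#: Fixed spike-in control sequence (synthetic 60-mer; first base is A so the
#: 5' G-run trimming never eats into it).
SPIKE_IN_SEQ = (
    "ATCAGTACCTGAACGTTCGATCCATGTACGATTCACGGATAATCCGTTAGCATCAGTTCA"
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Study conditions for the generator; defaults are the simulated
    equivalents of the experimental design (three biological replicates,
    low modification fractions, unfragmented 5'-end libraries)."""

    n_genes: int = 300
    gene_length: tuple[int, int] = (200, 400)
    utr_length: tuple[int, int] = (30, 90)
    yaag_fraction: float = 0.7
    nad_fraction: tuple[float, float] = (0.01, 0.05)
    null_fraction: float = 0.8  # genes with no NAD capping at all
    capture_efficiency: float = 0.5
    background_rate: float = 0.02
    reads_per_gene: int = 6000
    expression_sdlog: float = 0.4
    replicate_cv: float = 0.1  # biological variability between replicates
    n_replicates: int = 3
    small_rna_fraction: float = 0.05
    truncation_stop: float = 0.001
    truncation_factor: float = 3.0
    jitter: tuple[float, float, float] = (0.7, 0.1, 0.05)  # P(0), P(+-1), P(+-2)
    spike_in_copies: int = 100
    distal_offset: tuple[int, int] = (20, 45)
    proximal_offset: tuple[int, int] = (10, 25)
    distal_mix: float = 0.6
    within_gene_mix: bool = True  # False: each gene is all-distal or all-proximal
    transcriptome_rate: float = 0.2
    flank: int = 150
    enzymes: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ENZYMES.items()})
    strains: dict = field(default_factory=default_strains)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("yaag_fraction", "capture_efficiency", "background_rate",
                     "small_rna_fraction", "truncation_stop", "distal_mix",
                     "transcriptome_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.reads_per_gene <= 0:
            raise ValueError("reads_per_gene must be positive")

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["strains"] = {k: list(v) for k, v in self.strains.items()}
        return d


def effective_nad_fraction(truth: SimTruth, active: tuple[str, ...],
                           enzymes: dict | None = None) -> float:
    """Planted effective modification fraction rho' after decapping survival."""
    enzymes = enzymes or DEFAULT_ENZYMES
    sd = float(np.prod([enzymes[e]["distal"] for e in active])) if active else 1.0
    sp = float(np.prod([enzymes[e]["proximal"] for e in active])) if active else 1.0
    return truth.nad_fraction * (truth.distal_mix * sd + (1.0 - truth.distal_mix) * sp)


# ------------------------------------------------------------------ genome


def make_genome(config: SimConfig, rng: np.random.Generator
                ) -> tuple[dict[str, str], dict[str, GenomeAnnotation], list[SimTruth]]:
    """Build a toy single-chromosome genome with planted NAD promoters."""
    bases = np.array(list("ACGT"))
    blocks: list[np.ndarray] = []
    annots: dict[str, GenomeAnnotation] = {}
    truths: list[SimTruth] = []
    pos = 0
    expr = rng.lognormal(mean=0.0, sigma=config.expression_sdlog, size=config.n_genes)
    expr = expr / expr.mean()
    for i in range(config.n_genes):
        gene_id = f"g{i + 1:04d}"
        length = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
        utr = int(rng.integers(config.utr_length[0], config.utr_length[1] + 1))
        # the distal NAD TSS must stay inside both the counting window
        # (TLS-120) and the TSS scan window (canonical TSS - 50)
        dist_hi = min(config.distal_offset[1], 118 - utr, 45)
        dist_off = -int(rng.integers(config.distal_offset[0],
                                     max(dist_hi, config.distal_offset[0]) + 1))
        prox_hi = min(config.proximal_offset[1], utr - 5)
        prox_off = int(rng.integers(config.proximal_offset[0], max(prox_hi, config.proximal_offset[0]) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        is_null = rng.random() < config.null_fraction
        rho = 0.0 if is_null else float(rng.uniform(*config.nad_fraction))
        has_yaag = bool((not is_null) and rng.random() < config.yaag_fraction)

        block_len = config.flank + length + config.flank
        block = rng.choice(bases, size=block_len)
        sign = 1 if strand == "+" else -1
        if strand == "+":
            tss_local = config.flank
        else:
            tss_local = block_len - 1 - config.flank
        tls_local = tss_local + sign * utr
        tes_local = tss_local + sign * (length - 1)

        def put(local: int, base: str) -> None:
            block[local] = base if strand == "+" else base.translate(_COMPLEMENT)

        for off in (dist_off, prox_off):
            v = tss_local + sign * off
            if has_yaag:
                put(v - sign, "C" if rng.random() < 0.5 else "T")
                put(v, "A")
                put(v + sign, "A")
                put(v + 2 * sign, "G")
        # keep the first transcribed base of every variant non-G so the
        # 5' G-run trimming cannot eat into real inserts
        for off in (dist_off, prox_off, 0):
            v = tss_local + sign * off
            if (block[v] if strand == "+" else block[v].translate(_COMPLEMENT)) == "G":
                put(v, "A")

        annots[gene_id] = GenomeAnnotation(
            gene_id=gene_id, chrom="chr1", strand=strand,
            tls_pos=pos + tls_local, canonical_tss=pos + tss_local,
            tes_pos=pos + tes_local,
        )
        if config.within_gene_mix:
            mix = config.distal_mix
        else:
            mix = 1.0 if rng.random() < config.distal_mix else 0.0
        truths.append(SimTruth(
            gene_id=gene_id, nad_fraction=rho, distal_offset=dist_off,
            proximal_offset=prox_off, distal_mix=mix,
            has_yaag=has_yaag, truncation_factor=config.truncation_factor,
            expression=float(expr[i]),
        ))
        blocks.append(block)
        pos += block_len
    genome = {"chr1": "".join("".join(b) for b in blocks)}
    return genome, annots, truths


# ------------------------------------------------------------------- reads


def _jitter(rng: np.random.Generator, n: int, probs: tuple[float, float, float]) -> np.ndarray:
    p0, p1, p2 = probs
    kernel = np.array([p2, p1, p0, p1, p2], dtype=float)
    kernel /= kernel.sum()
    return rng.choice(np.arange(-2, 3), size=n, p=kernel)


def _emit_reads(rng, annots_df, gene_idx, five_offsets, is_nad, config, sample_id):
    """Turn per-read gene indices + transcript-oriented 5' offsets (from the
    canonical TSS) into genomic intervals with geometric 3'-truncation."""
    n = len(gene_idx)
    if n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "sample_id", "gene_id"])
    sign = annots_df["sign"].to_numpy()[gene_idx]
    tss = annots_df["canonical_tss"].to_numpy()[gene_idx]
    tes = annots_df["tes_pos"].to_numpy()[gene_idx]
    off = five_offsets + _jitter(rng, n, config.jitter)
    five = tss + sign * off
    span = (tes - five) * sign + 1
    q = np.where(is_nad, config.truncation_stop * config.truncation_factor,
                 config.truncation_stop)
    length = rng.geometric(np.clip(q, 1e-12, 1.0))
    length = np.clip(length, 18, span)  # normal-read regime; >=18 nt survive classification
    start = np.where(sign > 0, five, five - length + 1)
    end = start + length
    return pd.DataFrame({
        "chrom": annots_df["chrom"].to_numpy()[gene_idx],
        "start": start.astype(int),
        "end": end.astype(int),
        "strand": np.where(sign > 0, "+", "-"),
        "sample_id": sample_id,
        "gene_id": annots_df.index.to_numpy()[gene_idx],
    })


def _annots_frame(annots: dict[str, GenomeAnnotation]) -> pd.DataFrame:
    df = pd.DataFrame({
        "chrom": [a.chrom for a in annots.values()],
        "strand": [a.strand for a in annots.values()],
        "canonical_tss": [a.canonical_tss for a in annots.values()],
        "tls_pos": [a.tls_pos for a in annots.values()],
        "tes_pos": [a.tes_pos for a in annots.values()],
    }, index=list(annots.keys()))
    df["sign"] = np.where(df["strand"] == "+", 1, -1)
    return df


def simulate_reads(genome: dict[str, str], annots: dict[str, GenomeAnnotation],
                   truths: list[SimTruth], config: SimConfig, strain: str,
                   rng: np.random.Generator,
                   groups: tuple[str, ...] = ("S", "N"),
                   ) -> tuple[pd.DataFrame, pd.DataFrame, list[SampleMeta], dict]:
    """Simulate captured libraries for one strain.

    Returns ``(alignments, small_rnas, samples, manifest)``: a BED-like
    alignment table of normal reads, a small-RNA table (sequence-level,
    12-17 nt), the sample sheet, and a manifest of planted parameters.
    """
    if strain not in config.strains:
        raise ValueError(
            f"unknown strain {strain!r}; known: {sorted(config.strains)}")
    active = tuple(config.strains[strain])
    adf = _annots_frame(annots)
    tdf = pd.DataFrame([vars(t) for t in truths]).set_index("gene_id").loc[adf.index]

    rho = tdf["nad_fraction"].to_numpy()
    mix = tdf["distal_mix"].to_numpy()
    expr = tdf["expression"].to_numpy()
    s_d = float(np.prod([config.enzymes[e]["distal"] for e in active])) if active else 1.0
    s_p = float(np.prod([config.enzymes[e]["proximal"] for e in active])) if active else 1.0
    depth = np.maximum(1, np.round(config.reads_per_gene * expr)).astype(int)
    dist_off = tdf["distal_offset"].to_numpy()
    prox_off = tdf["proximal_offset"].to_numpy()
    n_genes = len(adf)

    frames, small_frames, samples = [], [], []
    manifest: dict = {"strain": strain, "active_enzymes": list(active),
                      "survival": {"distal": s_d, "proximal": s_p},
                      "samples": {}}
    for group in groups:
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{strain}_{group}{rep}"
            samples.append(SampleMeta(sample_id, strain, group, rep,
                                      "transcriptome" if group == "T" else "unfragmented"))
            cv = config.replicate_cv
            if cv > 0:
                bio = rng.lognormal(-cv * cv / 2.0, cv, size=n_genes)
                depth = np.maximum(1, np.round(
                    config.reads_per_gene * expr * bio)).astype(int)
            else:
                depth = np.maximum(1, np.round(
                    config.reads_per_gene * expr)).astype(int)
            if group == "T":
                # plain transcriptome library: uniform sampling, canonical 5' ends
                k_bg = rng.binomial(depth, config.transcriptome_rate)
                gi = np.repeat(np.arange(n_genes), k_bg)
                fr = _emit_reads(rng, adf, gi, np.zeros(len(gi), dtype=int),
                                 np.zeros(len(gi), dtype=bool), config, sample_id)
                frames.append(fr)
                manifest["samples"][sample_id] = {"normal": int(len(fr)), "small": 0}
                continue
            n_nad = rng.binomial(depth, rho)
            n_dist = rng.binomial(n_nad, mix)
            n_prox = n_nad - n_dist
            surv_d = rng.binomial(n_dist, s_d)
            surv_p = rng.binomial(n_prox, s_p)
            non_nad = depth - n_nad
            p_cap = config.capture_efficiency if group == "S" else config.background_rate
            k_d = rng.binomial(surv_d, p_cap)
            k_p = rng.binomial(surv_p, p_cap)
            k_bg = rng.binomial(non_nad, config.background_rate)

            gi = np.concatenate([np.repeat(np.arange(n_genes), k)
                                 for k in (k_d, k_p, k_bg)])
            offs = np.concatenate([
                np.repeat(dist_off, k_d),
                np.repeat(prox_off, k_p),
                np.zeros(int(k_bg.sum()), dtype=int),
            ])
            nad_mask = np.concatenate([
                np.ones(int(k_d.sum() + k_p.sum()), dtype=bool),
                np.zeros(int(k_bg.sum()), dtype=bool),
            ])
            fr = _emit_reads(rng, adf, gi, offs, nad_mask, config, sample_id)
            frames.append(fr)

            n_small = rng.poisson(config.small_rna_fraction * max(len(fr), 1))
            small = _emit_small_rnas(rng, genome, adf, tdf, n_small, sample_id, group)
            small_frames.append(small)
            manifest["samples"][sample_id] = {
                "normal": int(len(fr)), "small": int(len(small)),
                "spike_in": int(rng.poisson(config.spike_in_copies)),
            }
    alignments = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    small_rnas = (pd.concat(small_frames, ignore_index=True) if small_frames
                  else pd.DataFrame(columns=["sequence", "strand", "gene_id", "sample_id", "group"]))
    return alignments, small_rnas, samples, manifest


def _emit_small_rnas(rng, genome, adf, tdf, n, sample_id, group):
    """12-17 nt 5'-end prefixes of NAD TSS variants (abortive fragments)."""
    if n == 0:
        return pd.DataFrame(columns=["sequence", "strand", "gene_id", "sample_id", "group"])
    w = tdf["expression"].to_numpy() * tdf["nad_fraction"].to_numpy()
    if w.sum() == 0:
        w = tdf["expression"].to_numpy().astype(float)
    w = w / w.sum()
    gi = rng.choice(len(adf), size=n, p=w)
    lengths = rng.integers(12, 18, size=n)
    sign = adf["sign"].to_numpy()[gi]
    tss = adf["canonical_tss"].to_numpy()[gi]
    five = tss + sign * tdf["distal_offset"].to_numpy()[gi]
    chrom_seq = genome[adf["chrom"].iloc[0]]
    seqs = []
    for f, L, s in zip(five, lengths, sign):
        if s > 0:
            seqs.append(chrom_seq[f:f + L])
        else:
            seqs.append(revcomp(chrom_seq[f - L + 1:f + 1]))
    return pd.DataFrame({
        "sequence": seqs,
        "strand": np.where(sign > 0, "+", "-"),
        "gene_id": adf.index.to_numpy()[gi],
        "sample_id": sample_id,
        "group": group,
    })


# ------------------------------------------------------------------- FASTQ


import re as _re

_ADAPTER_PATTERN = _re.compile(r"C[ACGTN]{6}AGATCG")


def add_adapters(inserts: list[str], rng: np.random.Generator) -> list[str]:
    """Dress raw insert sequences as raw reads: a leading G-run (>=3 nt,
    3 + Poisson(2)), the insert, then the 3' adapter C + NNNNNN + AGATCG.

    The random hexamer is redrawn if it would create a spurious adapter
    match upstream of the true one, so trimming always recovers the insert.
    """
    bases = "ACGT"
    out = []
    g_runs = 3 + rng.poisson(2.0, size=len(inserts))
    for ins, g in zip(inserts, g_runs):
        ambiguous = _ADAPTER_PATTERN.search(ins) is not None
        while True:
            middle = "".join(bases[i] for i in rng.integers(0, 4, size=6))
            tail = ins + "C" + middle + "AGATCG"
            m = _ADAPTER_PATTERN.search(tail)
            if ambiguous or m.start() == len(ins):
                break
        out.append("G" * int(g) + tail)
    return out


def alignments_to_inserts(alignments: pd.DataFrame, genome: dict[str, str]) -> list[str]:
    """Recover the transcript-oriented insert sequence of each aligned read."""
    seqs = []
    for chrom, start, end, strand in zip(alignments["chrom"], alignments["start"],
                                         alignments["end"], alignments["strand"]):
        s = genome[chrom][start:end]
        seqs.append(s if strand == "+" else revcomp(s))
    return seqs


def reads_to_fastq(alignments: pd.DataFrame, small_rnas: pd.DataFrame,
                   genome: dict[str, str], config: SimConfig,
                   rng: np.random.Generator) -> dict[str, list[tuple[str, str]]]:
    """Build per-sample FASTQ records (id, sequence) with adapters, including
    small-RNA inserts and spike-in control reads."""
    per_sample: dict[str, list[str]] = {}
    ids: dict[str, list[str]] = {}
    for sample_id, sub in alignments.groupby("sample_id", sort=True):
        per_sample[sample_id] = alignments_to_inserts(sub, genome)
        ids[sample_id] = [f"{sample_id}:r{i}" for i in range(len(sub))]
    for sample_id, sub in small_rnas.groupby("sample_id", sort=True):
        per_sample.setdefault(sample_id, []).extend(sub["sequence"].tolist())
        ids.setdefault(sample_id, []).extend(
            f"{sample_id}:s{i}" for i in range(len(sub)))
    out: dict[str, list[tuple[str, str]]] = {}
    for sample_id in sorted(per_sample):
        inserts = per_sample[sample_id]
        n_spike = int(rng.poisson(config.spike_in_copies))
        spike_lens = rng.integers(20, len(SPIKE_IN_SEQ) + 1, size=n_spike)
        inserts = inserts + [SPIKE_IN_SEQ[:L] for L in spike_lens]
        rids = ids[sample_id] + [f"{sample_id}:is{i}" for i in range(n_spike)]
        raw = add_adapters(inserts, rng)
        out[sample_id] = list(zip(rids, raw))
    return out
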