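"""Read trimming, classification, toy mapping and feature counting.

Trimming follows the library chemistry: raw reads begin with a 5' G-run
(the read-through of the C-tailing step, G or N), carry the insert, and end
with the 3' adapter ``C NNNNNN AGATCG``.  Inserts shorter than 12 nt after
trimming are discarded; 12-17 nt inserts are "small RNA reads" and >=18 nt
inserts are "normal RNA reads" (the partition is exhaustive: exactly 18 nt
is normal).

The mapper is an exact seed-and-verify search over both strands with a
configurable mismatch budget (default 2), keeping a unique best hit;
equal-best ties are resolved to one location with a seeded RNG and counted
as multimapped, emulating single-placement reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeAnnotation, read_five_prime
from .simulate import SPIKE_IN_SEQ, revcomp

_ADAPTER_RE = re.compile(r"C[ACGTN]{6}AGATCG")
_LEAD_RE = re.compile(r"^[GN]+")
_VALID_RE = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    sequence: str
    length: int
    klass: str  # spike_in | small | normal | discarded
    adapter_found: bool = True


def trim_read(seq: str, read_id: str = "") -> TrimmedRead:
    """Strip the maximal leading G/N run and the first 3' adapter motif."""
    if not _VALID_RE.match(seq):
        raise ValueError(f"{read_id or seq}: non-ACGTN character")
    seq = _LEAD_RE.sub("", seq)
    m = _ADAPTER_RE.search(seq)
    adapter_found = m is not None
    insert = seq[: m.start()] if m else seq
    n = len(insert)
    if n < 12:
        klass = "discarded"
    elif n <= 17:
        klass = "small"
    else:
        klass = "normal"
    return TrimmedRead(read_id, insert, n, klass, adapter_found)


def classify_read(trimmed: TrimmedRead, spike_seq: str = SPIKE_IN_SEQ,
                  max_mismatch: int = 2) -> str:
    """Final class tag: spike-in reads are counted first, then by length."""
    if trimmed.klass == "discarded":
        return "discarded"
    s = trimmed.sequence
    if len(s) <= len(spike_seq):
        mism = sum(a != b for a, b in zip(s, spike_seq))
        if mism <= max_mismatch:
            return "spike_in"
    return trimmed.klass


def trim_and_classify(reads, spike_seq: str = SPIKE_IN_SEQ
                      ) -> tuple[list[TrimmedRead], dict[str, int]]:
    """Trim an iterable of (read_id, seq); returns records + class tallies."""
    out: list[TrimmedRead] = []
    tally = {"spike_in": 0, "small": 0, "normal": 0, "discarded": 0}
    for rid, seq in reads:
        t = trim_read(seq, rid)
        klass = classify_read(t, spike_seq)
        out.append(TrimmedRead(t.read_id, t.sequence, t.length, klass, t.adapter_found))
        tally[klass] += 1
    return out, tally


# -------------------------------------------------------------------- mapper


class ToyMapper:
    """Ungapped best-hit mapper over a small genome.

    Seeds are read chunks (pigeonhole over the mismatch budget); candidate
    placements are verified by Hamming distance.  Minus-strand hits are
    found by searching the reverse complement of the read on the forward
    genome.
    """

    def __init__(self, genome: dict[str, str]):
        self.genome = {k: v.upper() for k, v in genome.items()}

    def _find_candidates(self, chrom_seq: str, query: str, v: int) -> set[int]:
        n = len(query)
        if v == 0:
            hits, i = set(), chrom_seq.find(query)
            while i != -1:
                hits.add(i)
                i = chrom_seq.find(query, i + 1)
            return hits
        k = v + 1
        size = max(1, n // k)
        cands: set[int] = set()
        for c in range(k):
            lo = c * size
            hi = n if c == k - 1 else (c + 1) * size
            chunk = query[lo:hi]
            i = chrom_seq.find(chunk)
            while i != -1:
                p = i - lo
                if 0 <= p <= len(chrom_seq) - n:
                    cands.add(p)
                i = chrom_seq.find(chunk, i + 1)
        return cands

    def map_one(self, seq: str, v: int = 2) -> list[tuple[str, int, str, int]]:
        """All best placements as (chrom, start, strand, mismatches)."""
        hits: list[tuple[str, int, str, int]] = []
        best = v + 1
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for chrom, cseq in self.genome.items():
                for p in self._find_candidates(cseq, query, v):
                    mism = sum(a != b for a, b in zip(query, cseq[p:p + len(query)]))
                    if mism <= v:
                        hits.append((chrom, p, strand, mism))
                        best = min(best, mism)
        return [h for h in hits if h[3] == best]


def map_reads(trimmed: list[TrimmedRead], genome: dict[str, str],
              sample_id: str, rng: np.random.Generator, v: int = 2
              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map normal reads; ties go to one random placement and are tallied."""
    mapper = ToyMapper(genome)
    rows = []
    tally = {"mapped": 0, "unmapped": 0, "multimapped": 0}
    for t in trimmed:
        hits = mapper.map_one(t.sequence, v=v)
        if not hits:
            tally["unmapped"] += 1
            continue
        if len(hits) > 1:
            tally["multimapped"] += 1
            hits.sort()
            hit = hits[int(rng.integers(len(hits)))]
        else:
            hit = hits[0]
        chrom, p, strand, _ = hit
        rows.append((chrom, p, p + t.length, strand, sample_id))
        tally["mapped"] += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "sample_id"])
    return df, tally


def map_small_reads(trimmed: list[TrimmedRead], genome: dict[str, str],
                    sample_id: str, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Small reads are purged by zero-mismatch genome mapping."""
    return map_reads(trimmed, genome, sample_id, rng, v=0)


# ---------------------------------------------------------------- counting


def count_features(alignments: pd.DataFrame,
                   annots: dict[str, GenomeAnnotation],
                   window: tuple[int, int] = (-120, 65),
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count reads per gene over the 5'-UTR annotation window.

    A read is assigned to an mRNA gene when its 5' end lies within
    [TLS+window[0], TLS+window[1]] in transcript orientation on the matching
    strand (boundaries inclusive); windows of overlapping genes each receive
    the read.  Reads whose 5' end falls in rRNA/tRNA transcribed spans are
    tallied separately and excluded from the mRNA matrix.

    Returns ``(counts, excluded)``: a features x samples integer DataFrame
    and a per-class, per-sample tally of rRNA/tRNA reads.
    """
    lo, hi = window
    samples = sorted(alignments["sample_id"].unique())
    five = read_five_prime(alignments)
    key = pd.DataFrame({
        "sample_id": alignments["sample_id"].to_numpy(),
        "chrom": alignments["chrom"].to_numpy(),
        "strand": alignments["strand"].to_numpy(),
        "five": five.to_numpy(),
    })
    sorted_pos: dict[tuple[str, str, str], np.ndarray] = {}
    for (s, c, st), sub in key.groupby(["sample_id", "chrom", "strand"], sort=True):
        sorted_pos[(s, c, st)] = np.sort(sub["five"].to_numpy())

    mrna = {gid: a for gid, a in annots.items()
            if a.gene_class not in ("rRNA", "tRNA")}
    counts = pd.DataFrame(0, index=sorted(mrna), columns=samples, dtype=int)
    for gid in counts.index:
        a = mrna[gid]
        g_lo = min(a.tls_pos + lo * a.sign, a.tls_pos + hi * a.sign)
        g_hi = max(a.tls_pos + lo * a.sign, a.tls_pos + hi * a.sign)
        for s in samples:
            pos = sorted_pos.get((s, a.chrom, a.strand))
            if pos is None:
                continue
            counts.at[gid, s] = int(np.searchsorted(pos, g_hi, "right")
                                    - np.searchsorted(pos, g_lo, "left"))
    excl_rows = []
    for gid, a in annots.items():
        if a.gene_class not in ("rRNA", "tRNA"):
            continue
        g_lo = min(a.canonical_tss, a.tes_pos)
        g_hi = max(a.canonical_tss, a.tes_pos)
        for s in samples:
            pos = sorted_pos.get((s, a.chrom, a.strand))
            n = 0 if pos is None else int(np.searchsorted(pos, g_hi, "right")
                                          - np.searchsorted(pos, g_lo, "left"))
            excl_rows.append((gid, a.gene_class, s, n))
    excluded = pd.DataFrame(excl_rows, columns=["gene_id", "gene_class", "sample_id", "count"])
    return counts, excluded
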