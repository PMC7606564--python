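"""Simulate the knockout-strain lattice and score decapping hierarchies.

Convenience driver used by the CLI and by recovery tests: it simulates the
triple knockout, the three double knockouts (one enzyme back) and the three
single knockouts (two enzymes back), runs enrichment per strain and TLI of
each double knockout against the triple, and feeds everything to
``hierarchy.enumerate_paths``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import enrich, hierarchy, readproc, tss
from .core import samples_to_frame
from .simulate import ENZYMES, SimConfig, make_genome, simulate_reads


def strain_name(active: tuple[str, ...]) -> str:
    deleted = sorted(e for e in ENZYMES if e not in active)
    return "_".join(f"{e}d" for e in deleted) if deleted else "wt"


def run_lattice(config: SimConfig, rng: np.random.Generator,
                tli_min: float = 0.1, fdr_max: float = 0.1,
                r_min: float = 2.0,
                enzymes: tuple[str, ...] = ENZYMES) -> pd.DataFrame:
    """One full lattice simulation; returns the scored path table."""
    genome, annots, truths = make_genome(config, rng)
    active_sets = [()] + [(e,) for e in enzymes] + [
        tuple(sorted(p)) for p in itertools.combinations(enzymes, 2)]

    aln: dict[tuple[str, ...], pd.DataFrame] = {}
    s_ids: dict[tuple[str, ...], list[str]] = {}
    enr_tables: dict[tuple[str, ...], pd.DataFrame] = {}
    for active in active_sets:
        name = strain_name(active)
        reads, _small, samples, _man = simulate_reads(
            genome, annots, truths, config, name, rng)
        meta = samples_to_frame(samples)
        aln[active] = reads
        s_ids[active] = meta.loc[meta["group"] == "S", "sample_id"].tolist()
        counts, _ = readproc.count_features(reads, annots)
        enr_tables[active] = enrich.enrichment_test(counts, meta, strain=name)

    tli_tables = {
        (e,): tss.tli_table(aln[()], aln[(e,)], annots,
                            s_ids[()], s_ids[(e,)],
                            tli_min=tli_min, fdr_max=fdr_max)
        for e in enzymes}
    return hierarchy.enumerate_paths(tli_tables, enr_tables, enzymes,
                                     tli_min=tli_min, fdr_max=fdr_max,
                                     r_min=r_min)
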