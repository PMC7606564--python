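"""Decapping-enzyme hierarchy inference over the knockout-strain lattice.

Starting from the triple knockout (no NAD decapping), enzymes are "added
back" one at a time by moving to the matching double and single knockouts.
A species supports the ordered path (E1, E2) when reintroducing E1 shifts
its transcript leader (|TLI| > 0.1, FDR < 0.1: E1 removes one TL class)
and reintroducing E2 then removes it from the enriched fraction or cuts
its enrichment at least ``r_min``-fold (E2 removes the remainder).  Paths
are scored by the number of such resolved species.
"""

from __future__ import annotations

import itertools
import logging

import pandas as pd

log = logging.getLogger("nadscape")


def tl_shift_species(tli: pd.DataFrame, tli_min: float = 0.1,
                     fdr_max: float = 0.1) -> pd.DataFrame:
    """Species with a significant TL shift, tagged distal/proximal."""
    if tli.empty:
        return pd.DataFrame(columns=["gene_id", "tli", "fdr", "direction"])
    hit = tli[(tli["fdr"] < fdr_max) & (tli["tli"].abs() > tli_min)].copy()
    hit["direction"] = hit["tli"].map(lambda v: "distal" if v > 0 else "proximal")
    return hit[["gene_id", "tli", "fdr", "direction"]].reset_index(drop=True)


def resolved_species(shifted: pd.DataFrame, enr_plus_one: pd.DataFrame,
                     enr_plus_two: pd.DataFrame, r_min: float = 2.0) -> pd.DataFrame:
    """Subset of shifted species that are enriched after the first enzyme
    but disappear (or drop >= r_min-fold in FC) after the second."""
    e1 = enr_plus_one.set_index("feature_id")
    e2 = enr_plus_two.set_index("feature_id")
    rows = []
    for row in shifted.itertuples():
        gid = row.gene_id
        if gid not in e1.index or e1.at[gid, "verdict"] != "enriched":
            continue
        if gid not in e2.index:
            rows.append((gid, row.direction, "absent"))
            continue
        lost = e2.at[gid, "verdict"] != "enriched"
        dropped = e1.at[gid, "fc"] / max(e2.at[gid, "fc"], 1e-12) >= r_min
        if lost or dropped:
            rows.append((gid, row.direction, "lost" if lost else "reduced"))
    return pd.DataFrame(rows, columns=["gene_id", "direction", "reason"])


def enumerate_paths(tli_tables: dict[tuple[str, ...], pd.DataFrame],
                    enrich_tables: dict[tuple[str, ...], pd.DataFrame],
                    enzymes: tuple[str, ...] = ("rai1", "dxo1", "npy1"),
                    tli_min: float = 0.1, fdr_max: float = 0.1,
                    r_min: float = 2.0) -> pd.DataFrame:
    """Score all ordered enzyme pairs across the strain lattice.

    Strains are keyed by the sorted tuple of *active* enzymes: the triple
    knockout is ``()``, reintroducing E1 gives ``(E1,)`` and so on.
    ``tli_tables[(E1,)]`` holds the TLI of strain (E1,) relative to the
    triple knockout.  Missing strains drop their paths with a warning.
    """
    rows = []
    for e1, e2 in itertools.permutations(enzymes, 2):
        k1 = (e1,)
        k2 = tuple(sorted((e1, e2)))
        if k1 not in tli_tables or k1 not in enrich_tables or k2 not in enrich_tables:
            log.warning("enumerate_paths: missing tables for %s -> %s, "
                        "path omitted", e1, e2)
            continue
        shifted = tl_shift_species(tli_tables[k1], tli_min, fdr_max)
        resolved = resolved_species(shifted, enrich_tables[k1],
                                    enrich_tables[k2], r_min)
        rows.append((
            e1, e2, len(shifted),
            int((shifted["direction"] == "distal").sum()),
            int((shifted["direction"] == "proximal").sum()),
            len(resolved),
        ))
    return pd.DataFrame(rows, columns=[
        "first_enzyme", "second_enzyme", "n_shifted", "n_shifted_distal",
        "n_shifted_proximal", "n_resolved"])
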