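"""End-to-end convenience: simulated cohort -> identification -> table.

Glue used by the CLI, the acceptance script and the end-to-end tests: run
the full identification pipeline over a synthetic multi-species cohort and
assemble the species x family percentage table exactly as one would from
real proteomes.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from receptoire.io import select_primary_transcripts
from receptoire.rules import (
    DEFAULT_THRESHOLDS,
    ReferenceKinasePanel,
    RuleThresholds,
    identify_repertoire,
)
from receptoire.simulate import SimulationConfig, simulate_counts, simulate_proteome
from receptoire.stats import RepertoireTable, compute_percentages

__all__ = ["simulated_cohort_table"]


def simulated_cohort_table(
    cfg: SimulationConfig,
    seed: Optional[int] = None,
    panel: Optional[ReferenceKinasePanel] = None,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    latent: Optional[pd.Series] = None,
    clade: str = "angiosperm",
) -> tuple[RepertoireTable, pd.DataFrame]:
    """Simulate a cohort, identify every proteome, return the built table.

    Returns ``(table, true_counts)`` where `table` is the
    :class:`RepertoireTable` assembled from the pipeline's own calls and
    `true_counts` the generator's planted counts, for comparison.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    counts_true, totals, truth = simulate_counts(cfg, rng=rng, latent=latent)
    rows = {}
    subgroup_rows = {} if panel is not None else None
    for species in counts_true.index:
        sim = simulate_proteome(
            counts_true.loc[species], cfg, rng=rng,
            total=int(totals.loc[species]), panel=panel, with_loci=False,
        )
        primary = select_primary_transcripts(sim.proteins)
        res = identify_repertoire(primary, sim.hits, sim.tm, thresholds, panel)
        rows[species] = dict(res.counts, searched_total=res.searched_total)
        if subgroup_rows is not None:
            subgroup_rows[species] = {
                f"LRR-RLK-{sg}": n for sg, n in res.subgroup_counts.items()
            }
    found = pd.DataFrame.from_dict(rows, orient="index")
    found_totals = found.pop("searched_total")
    clades = pd.Series(clade, index=found.index)
    sub = None
    if subgroup_rows is not None:
        sub = pd.DataFrame.from_dict(subgroup_rows, orient="index").fillna(0)
    table = compute_percentages(found, found_totals, clades, sub)
    return table, counts_true
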