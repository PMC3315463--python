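"""End-to-end screen pipeline: quantify -> normalize -> SAM -> rank -> enrich.

This is the programmatic equivalent of the ``run-all`` command: it wires
the stage modules together on tidy tables and returns every intermediate
and final result, keyed by name, ready for :func:`splicescreen.io.write_results`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .analysis import (
    candidate_report,
    composite_rank,
    rank_strains,
    splicing_efficiency,
)
from .io import PrimerPanel
from .normalize import normalize_screen, rel_wide
from .quant import fit_curves, quantify
from .sam import sam_analysis

logger = logging.getLogger(__name__)


def strain_summaries(records: pd.DataFrame, target_id: str) -> pd.Series:
    """Per-strain summary for ranking: mean of log2 Rel over the replicates."""
    wide = rel_wide(records, target_id)
    return np.log2(wide).mean(axis=1)


def run_pipeline(
    cp_table: pd.DataFrame,
    curve_points: pd.DataFrame,
    panel: PrimerPanel,
    cv_max: float = 0.25,
    log2_cnorm_min: float = -3.0,
    min_refs: int = 4,
    cnorm_method: str = "geometric",
    mu0: float = 0.0,
    delta: float | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    min_rank_targets: int = 3,
    gene_sets: dict | None = None,
    top_ns=(50, 100, 200),
    efficiency_pair: tuple | None = None,
) -> dict:
    """Run the whole analysis on a Cp table with per-target standard curves.

    ``efficiency_pair`` names the (precursor, total) targets of the
    splicing-efficiency index; when None it is inferred from the panel if
    exactly one total target is declared and a precursor for the same
    transcript prefix exists (e.g. TEF5_pre / TEF5_total).

    Returns a dict of result tables plus the fitted per-target SAM models
    under ``sam_models``.
    """
    panel.require_references(min_refs)
    curves = fit_curves(curve_points)
    quants = quantify(cp_table, curves)
    records, diagnostics = normalize_screen(
        quants,
        reference_targets=panel.reference_targets,
        cv_max=cv_max,
        log2_cnorm_min=log2_cnorm_min,
        min_refs=min_refs,
        method=cnorm_method,
    )

    precursors = [t for t in panel.precursor_targets if t in set(cp_table["target_id"])]
    sam_models = {}
    sam_tables = {}
    for target in precursors:
        wide = np.log2(rel_wide(records, target))
        model = sam_analysis(
            wide, mu0=mu0, delta=delta, n_permutations=n_permutations, seed=seed
        )
        sam_models[target] = model
        sam_tables[target] = model.result_table()
        logger.info(
            "SAM %s: s0=%.4g delta=%.4g fdr=%.4g called=%d",
            target,
            model.s0_,
            model.delta_,
            model.fdr_,
            model.n_called_,
        )

    ranks = pd.DataFrame(
        {t: rank_strains(strain_summaries(records, t)) for t in precursors}
    )
    composite = composite_rank(ranks, min_targets=min_rank_targets)

    efficiency = pd.DataFrame()
    if efficiency_pair is None:
        # the total-RNA target may double as a normalization reference
        # (Tef5 mRNA does), so search reference targets too
        totals = panel.total_targets or [
            t for t in panel.reference_targets if t.endswith("_total")
        ]
        if len(totals) == 1:
            prefix = totals[0].rsplit("_", 1)[0]
            match = [t for t in precursors if t.startswith(prefix)]
            if match:
                efficiency_pair = (match[0], totals[0])
    if efficiency_pair is not None:
        prec_t, total_t = efficiency_pair
        prec = 2.0 ** strain_summaries(records, prec_t)
        total = 2.0 ** strain_summaries(records, total_t)
        both = pd.concat(
            [prec.rename("rel_precursor"), total.rename("rel_total")], axis=1
        ).dropna()
        both["efficiency_index"] = splicing_efficiency(
            both["rel_precursor"], both["rel_total"]
        )
        efficiency = both

    report = candidate_report(
        sam_tables, composite=composite, gene_sets=gene_sets, top_ns=top_ns
    )

    operating_points = pd.DataFrame(
        [
            {
                "target_id": t,
                "s0": m.s0_,
                "delta": m.delta_,
                "fdr": m.fdr_,
                "n_called": m.n_called_,
                "n_positive": int((m.calls_ == "positive").sum()),
                "n_negative": int((m.calls_ == "negative").sum()),
                "n_permutations": m.n_permutations_,
                "exhaustive": m.exhaustive_,
            }
            for t, m in sam_models.items()
        ]
    )

    results = {
        "records": records,
        "diagnostics": diagnostics,
        "ranks": ranks.reset_index(names="strain_id"),
        "composite_rank": composite.reset_index(names="strain_id"),
        "efficiency": efficiency.reset_index(names="strain_id")
        if len(efficiency)
        else efficiency,
        "operating_points": operating_points,
        "candidates": report["candidates"].reset_index(names="strain_id"),
        "enrichment": report["enrichment"],
    }
    for target, table in sam_tables.items():
        results[f"sam_{target}"] = table
    results["sam_models"] = sam_models
    return results
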