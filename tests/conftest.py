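import numpy as np
import pandas as pd
import pytest

import splicescreen as ss


@pytest.fixture(scope="session")
def small_screen():
    """A 300-strain synthetic screen with 5% spiked strains."""
    config = ss.SimulationConfig(
        n_strains=300, frac_spiked=0.05, spike_log2_effect=2.0, tech_cv=0.05, seed=7
    )
    return ss.generate_screen(config)


@pytest.fixture(scope="session")
def small_screen_results(small_screen):
    """Quantified + normalized records of the small screen."""
    config = small_screen.config
    curves = ss.fit_curves(small_screen.curve_points)
    quants = ss.quantify(small_screen.cp_table, curves)
    records, diagnostics = ss.normalize_screen(
        quants, reference_targets=config.panel().reference_targets
    )
    return {"quants": quants, "records": records, "diagnostics": diagnostics}


def hand_plate(values_by_sample, target_ids, plate_id="P1"):
    """Build a tidy quant table from per-sample per-target values.

    values_by_sample: {(strain, bio_rep): {target: ng or [ng per tech rep]}}
    """
    rows = []
    wells = iter(f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 25))
    for (strain, bio), levels in values_by_sample.items():
        well = next(wells)
        for target in target_ids:
            ng = levels[target]
            ngs = ng if isinstance(ng, (list, tuple)) else [ng, ng]
            for tech, v in enumerate(ngs, start=1):
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well": well,
                        "strain_id": strain,
                        "target_id": target,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "cp": np.nan,
                        "ng": v,
                    }
                )
    return pd.DataFrame(rows)
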