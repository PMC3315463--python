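"""Synthetic QPCR screens with the statistical structure the pipeline assumes.

The generator emulates a genome-wide yeast splicing screen: ~5500 mutant
strains grown in 384-well plates, two biological replicates each measured
with two technical QPCR replicates, a panel of six reference RNAs spanning
a ~300-fold abundance range, five precursor reporters plus a total-RNA
target, per-sample RNA-yield variation (log-normal, variance 1.5 in log2
by default), per-plate batch offsets, and a configurable fraction of
"spiked" strains whose precursor levels are elevated — a pure splicing
defect leaves the total-RNA target untouched, while the transcriptional
spike mode raises precursor and total together.

All noise is multiplicative (log-normal): QPCR errors act on quantities,
and the screen's diagnostics all live in log2 space.  True quantities are
converted to Cp values through per-target standard curves whose slopes sit
in the 86-97% efficiency band, and ground truth (per-strain effects,
per-sample yields, per-plate offsets) is returned alongside every dataset
so parameter recovery is testable.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import PrimerPanel, write_results

PLATE_ROWS = string.ascii_uppercase[:16]
PLATE_COLS = range(1, 25)
WELLS_PER_PLATE = 384

#: default reference panel, relative abundances spanning 300-fold
DEFAULT_REFERENCE_ABUNDANCES = {
    "U1_snRNA": 600.0,
    "SCR1": 250.0,
    "TEF5_total": 90.0,
    "TUB1": 30.0,
    "SRB2": 6.0,
    "FAA1": 2.0,
}

#: default assay targets: the five canonical precursor reporters, with
#: abundances relative to the least-abundant transcript (TUB3 precursor = 1)
DEFAULT_TARGET_ABUNDANCES = {
    "U3_pre": 20.0,
    "RPL31B_pre": 2.5,
    "UBC13_pre": 2.0,
    "TEF5_pre": 1.5,
    "TUB3_pre": 1.0,
}

#: per-target standard-curve slopes, cycles per log10 quantity; the values
#: cycle through the 86-97% amplification-efficiency band
DEFAULT_SLOPES = (-3.42, -3.50, -3.58, -3.65, -3.71)
DEFAULT_INTERCEPT = 24.0


@dataclass
class SimulationConfig:
    """Parameters of a synthetic screen.

    Defaults encode the screen being emulated: 5500 strains, 2 biological
    x 2 technical replicates, six references over a ~300-fold range,
    per-sample log2 yield sd sqrt(1.5), per-plate batch sd 0.25 log2,
    technical CV 0.05, 1% dropout.
    """

    n_strains: int = 5500
    n_plates: int | None = None  # per bio rep; derived from n_strains when None
    frac_spiked: float = 0.02
    spike_log2_effect: float | tuple = 2.0
    spike_mode: str = "splicing"  # or "transcription"
    reference_abundances: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_ABUNDANCES)
    )
    target_abundances: dict = field(
        default_factory=lambda: dict(DEFAULT_TARGET_ABUNDANCES)
    )
    yield_log2_sd: float = math.sqrt(1.5)
    plate_log2_sd: float = 0.25
    tech_cv: float = 0.05
    dropout_rate: float = 0.01
    curve_slopes: dict = field(default_factory=dict)
    curve_intercepts: dict = field(default_factory=dict)
    n_bio_reps: int = 2
    n_tech_reps: int = 2
    seed: int = 0

    def __post_init__(self):
        for rate in (self.frac_spiked, self.dropout_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for sd in (self.yield_log2_sd, self.plate_log2_sd, self.tech_cv):
            if sd < 0:
                raise ValueError("noise magnitudes must be >= 0")
        for name, a in {**self.reference_abundances, **self.target_abundances}.items():
            if a <= 0:
                raise ValueError(f"abundance of {name!r} must be positive")
        if self.spike_mode not in ("splicing", "transcription"):
            raise ValueError(f"unknown spike_mode {self.spike_mode!r}")

    @property
    def all_targets(self) -> list:
        return list(self.reference_abundances) + [
            t for t in self.target_abundances if t not in self.reference_abundances
        ]

    def panel(self) -> PrimerPanel:
        roles = {t: "reference" for t in self.reference_abundances}
        for t in self.target_abundances:
            if t not in roles:
                roles[t] = "total" if t.endswith("_total") else "precursor"
        return PrimerPanel(roles)


@dataclass
class SyntheticScreen:
    """A generated dataset plus its ground truth."""

    plate_map: pd.DataFrame
    cp_table: pd.DataFrame
    curve_points: pd.DataFrame
    strain_truth: pd.DataFrame
    plate_truth: pd.DataFrame
    config: SimulationConfig


def spike_reference_panel(
    n_targets: int = 6, span: float = 300.0, labels=None
) -> dict:
    """Reference abundances relative to the least-abundant member (value 1),
    log-spaced over the requested fold range (default ~300-fold)."""
    if span <= 1:
        raise ValueError("abundance span must exceed 1")
    values = np.logspace(0, np.log10(span), n_targets)[::-1]
    if labels is None:
        labels = list(DEFAULT_REFERENCE_ABUNDANCES)[:n_targets]
    if len(labels) != n_targets:
        raise ValueError("need one label per reference target")
    return {lab: float(v) for lab, v in zip(labels, values)}


def _well_labels() -> list:
    return [f"{r}{c:02d}" for r in PLATE_ROWS for c in PLATE_COLS]


def generate_screen(config: SimulationConfig) -> SyntheticScreen:
    """Generate a complete synthetic screen, deterministically from the seed.

    True quantity per sample and target:

        q = abundance * 2**effect * yield * 2**plate_offset

    with the spike effect applied to precursor targets (and to total
    targets in transcriptional spike mode) of spiked strains only.  Each
    technical replicate multiplies q by log-normal noise of coefficient of
    variation ``tech_cv`` before conversion to Cp through the target's
    standard curve; dropout deletes Cp values independently per well.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    strains = np.array([f"strain{i:05d}" for i in range(1, n + 1)])
    bio_reps = [chr(ord("A") + i) for i in range(config.n_bio_reps)]

    needed = math.ceil(n / WELLS_PER_PLATE)
    n_plates = needed if config.n_plates is None else config.n_plates
    if n_plates * WELLS_PER_PLATE < n:
        raise ValueError(
            f"{n} strains exceed the capacity of {n_plates} 384-well plates; "
            f"{needed} plates required"
        )
    wells = _well_labels()

    # spiked strains and their per-target effects
    n_spiked = int(round(config.frac_spiked * n))
    spiked_idx = rng.choice(n, size=n_spiked, replace=False)
    spiked = np.zeros(n, dtype=bool)
    spiked[spiked_idx] = True
    effect_spec = config.spike_log2_effect
    if np.isscalar(effect_spec):
        effects = np.where(spiked, float(effect_spec), 0.0)
    else:
        lo, hi = effect_spec
        effects = np.where(spiked, rng.uniform(lo, hi, size=n), 0.0)

    # assignment: row-major within plates, same layout for every bio rep
    plate_of_strain = np.arange(n) // WELLS_PER_PLATE
    well_of_strain = np.array([wells[i % WELLS_PER_PLATE] for i in range(n)])

    # per-target curves
    targets = config.all_targets
    slopes = {
        t: config.curve_slopes.get(t, DEFAULT_SLOPES[i % len(DEFAULT_SLOPES)])
        for i, t in enumerate(targets)
    }
    intercepts = {
        t: config.curve_intercepts.get(t, DEFAULT_INTERCEPT) for t in targets
    }
    abundances = {**config.reference_abundances, **config.target_abundances}

    spike_roles = {t: t in config.target_abundances for t in targets}
    if config.spike_mode == "transcription":
        for t in targets:
            if t.endswith("_total"):
                spike_roles[t] = True

    # per-sample yields and per-plate offsets
    plate_ids = np.array(
        [f"P{p + 1:02d}{b}" for b in bio_reps for p in range(n_plates)]
    )
    plate_offsets = rng.normal(0.0, config.plate_log2_sd, size=plate_ids.size)
    plate_offset_of = dict(zip(plate_ids, plate_offsets))
    yields = 2.0 ** rng.normal(
        0.0, config.yield_log2_sd, size=(n, config.n_bio_reps)
    )

    # log-normal technical noise with the requested CV on the linear scale
    sigma_ln = math.sqrt(math.log(1.0 + config.tech_cv**2))

    frames = []
    map_rows = []
    for bi, bio in enumerate(bio_reps):
        plate = np.array([f"P{p + 1:02d}{bio}" for p in plate_of_strain])
        offset = np.array([plate_offset_of[p] for p in plate])
        map_rows.append(
            pd.DataFrame(
                {
                    "plate_id": plate,
                    "well": well_of_strain,
                    "strain_id": strains,
                    "bio_rep": bio,
                }
            )
        )
        for target in targets:
            base = abundances[target]
            eff = effects if spike_roles[target] else 0.0
            q_true = base * 2.0 ** np.asarray(eff) * yields[:, bi] * 2.0**offset
            for tech in range(1, config.n_tech_reps + 1):
                noise = np.exp(
                    rng.normal(-0.5 * sigma_ln**2, sigma_ln, size=n)
                )
                q = q_true * noise
                cp = slopes[target] * np.log10(q) + intercepts[target]
                drop = rng.random(n) < config.dropout_rate
                cp = np.where(drop, np.nan, cp)
                frames.append(
                    pd.DataFrame(
                        {
                            "plate_id": plate,
                            "well": well_of_strain,
                            "strain_id": strains,
                            "target_id": target,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "cp": cp,
                        }
                    )
                )
    cp_table = pd.concat(frames, ignore_index=True)
    plate_map = pd.concat(map_rows, ignore_index=True)

    # standard-curve dilution series: 4-fold steps, 7 points, slight noise
    curve_rows = []
    quantities = 32.0 * 0.25 ** np.arange(7)
    for target in targets:
        cp_pts = (
            slopes[target] * np.log10(quantities)
            + intercepts[target]
            + rng.normal(0.0, 0.02, size=quantities.size)
        )
        curve_rows.append(
            pd.DataFrame(
                {
                    "target_id": target,
                    "known_quantity": quantities,
                    "cp": cp_pts,
                }
            )
        )
    curve_points = pd.concat(curve_rows, ignore_index=True)

    strain_truth = pd.DataFrame(
        {
            "strain_id": strains,
            "spiked": spiked,
            "log2_effect": effects,
            **{
                f"yield_{bio}": yields[:, bi]
                for bi, bio in enumerate(bio_reps)
            },
        }
    )
    plate_truth = pd.DataFrame(
        {"plate_id": plate_ids, "log2_offset": plate_offsets}
    )
    return SyntheticScreen(
        plate_map=plate_map,
        cp_table=cp_table,
        curve_points=curve_points,
        strain_truth=strain_truth,
        plate_truth=plate_truth,
        config=config,
    )


def write_fixture(screen: SyntheticScreen, out_dir) -> pd.DataFrame:
    """Write a generated screen plus its ground truth and config to disk."""
    manifest = write_results(
        {
            "plate_map": screen.plate_map,
            "cp_table": screen.cp_table,
            "curve_points": screen.curve_points,
            "strain_truth": screen.strain_truth,
            "plate_truth": screen.plate_truth,
        },
        out_dir,
    )
    cfg = asdict(screen.config)
    cfg["spike_log2_effect"] = (
        list(cfg["spike_log2_effect"])
        if isinstance(cfg["spike_log2_effect"], tuple)
        else cfg["spike_log2_effect"]
    )
    from pathlib import Path

    with open(Path(out_dir) / "config.json", "w") as fh:
        # key order preserved: target iteration order shapes the RNG stream
        json.dump(cfg, fh, indent=2)
    return manifest
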