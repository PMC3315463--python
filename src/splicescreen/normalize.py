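"""Composite multi-reference normalization of screen quantities.

Every sample (one biological replicate of one strain, in one well of one
plate) carries measurements of six reference RNAs whose cellular levels
span a ~300-fold range.  Dividing each reference quantity by the per-plate,
per-primer median and averaging the six ratios gives a composite
normalization constant C_norm — a per-sample scalar for total RNA yield
that cancels per-plate batch effects.  Normalized levels are measurement
quantities divided by the sample's C_norm; relative levels (Rel) divide
those by the per-plate median of normalized levels, so the typical strain
sits at Rel = 1.

Quality filters:

* replicate CV filter — a sample is dropped for a target whose technical
  replicates have coefficient of variation > 0.25 (linear ng scale), and
  dropped entirely if any reference target fails;
* C_norm filter — samples with log2(C_norm) < -3 (an 8-fold drop from the
  plate median, i.e. very little cDNA) are dropped.

Both thresholds are strict: the boundary values pass.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

CV_MAX = 0.25
LOG2_CNORM_MIN = -3.0
MIN_REFS = 4

SAMPLE_KEY = ["plate_id", "strain_id", "bio_rep"]


def replicate_cv(values) -> float:
    """Coefficient of variation of replicate quantities (linear scale).

    Sample standard deviation (ddof=1) divided by the mean.  Fewer than two
    non-missing values yield NaN (an undetermined CV); a zero mean is an
    error.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        raise ValueError("zero mean: CV undefined")
    return float(v.std(ddof=1) / m)


def plate_medians(quants: pd.DataFrame, value_col: str = "ng") -> pd.Series:
    """Per-(plate, target) median of non-missing values.

    Even-sized groups use the midpoint of the two central values.  Groups
    with no non-missing values are absent from the result.
    """
    ok = quants.dropna(subset=[value_col])
    return ok.groupby(["plate_id", "target_id"])[value_col].median()


def compute_cnorm(
    sample_refs: dict,
    medians: dict,
    min_refs: int = MIN_REFS,
    method: str = "geometric",
) -> float:
    """Composite normalization constant from per-reference ratios.

    Each ratio is the sample's reference quantity over the per-plate,
    per-primer median.  Ratios are averaged with a geometric mean by
    default (log2(C_norm) is normally distributed across a screen, and the
    geometric mean makes single-sample yield invariance exact); arithmetic
    mean and median are available alternatives.

    Returns NaN when fewer than *min_refs* ratios are available.
    """
    ratios = []
    for target, ng in sample_refs.items():
        med = medians.get(target)
        if med is None or ng is None or np.isnan(ng) or np.isnan(med):
            continue
        r = ng / med
        if r <= 0:
            raise ValueError(f"nonpositive reference ratio for target {target!r}")
        ratios.append(r)
    if len(ratios) < min_refs:
        return float("nan")
    return _aggregate(np.asarray(ratios), method)


def _aggregate(ratios: np.ndarray, method: str) -> float:
    if method == "geometric":
        return float(np.exp(np.mean(np.log(ratios))))
    if method == "arithmetic":
        return float(np.mean(ratios))
    if method == "median":
        return float(np.median(ratios))
    raise ValueError(f"unknown C_norm aggregation method {method!r}")


def apply_cnorm_filter(cnorm: float, log2_cnorm_min: float = LOG2_CNORM_MIN) -> bool:
    """True when the sample passes the low-yield filter.

    Pass iff log2(C_norm) >= the threshold; only values strictly below
    fail, so the 8-fold-decrease boundary itself passes.
    """
    if not cnorm > 0:
        raise ValueError("C_norm must be positive")
    return bool(np.log2(cnorm) >= log2_cnorm_min)


def normalize_screen(
    quants: pd.DataFrame,
    reference_targets,
    cv_max: float = CV_MAX,
    log2_cnorm_min: float = LOG2_CNORM_MIN,
    min_refs: int = MIN_REFS,
    method: str = "geometric",
    strict_cv: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full filter + normalization cascade on a quantified screen.

    Parameters
    ----------
    quants : DataFrame
        Tidy measurement table with columns plate_id, well, strain_id,
        bio_rep, tech_rep, target_id, ng (one row per technical replicate).
    reference_targets : sequence of target ids forming the composite.
    strict_cv : bool
        When True, a target whose CV cannot be computed (a single
        surviving replicate) fails the CV filter instead of passing.

    Returns
    -------
    records : DataFrame
        The input rows plus ``cv``, ``cv_pass``, ``cnorm``, ``cnorm_pass``,
        ``sample_pass``, ``normalized_level`` and ``rel`` columns.  Rows of
        failing samples keep their flags but carry NaN levels.
    diagnostics : DataFrame
        One row per sample: C_norm, log2(C_norm), number of reference
        ratios used, and the filter flags.
    """
    reference_targets = list(reference_targets)
    if not reference_targets:
        raise ValueError("at least one reference target is required")
    df = quants.copy()

    # CV per sample and target, across technical replicates (vectorized
    # equivalent of replicate_cv: NaN below two values, sd/mean otherwise)
    grp = df.groupby(SAMPLE_KEY + ["target_id"])["ng"]
    mean_ng = grp.mean().rename("mean_ng")
    sd = grp.std(ddof=1)
    n_vals = grp.count()
    if ((n_vals >= 2) & (mean_ng == 0)).any():
        raise ValueError("zero replicate mean: CV undefined")
    cv = (sd / mean_ng).where(n_vals >= 2).rename("cv")
    per_target = pd.concat([cv, mean_ng], axis=1).reset_index()
    if strict_cv:
        per_target["cv_pass"] = per_target["cv"] <= cv_max
    else:
        per_target["cv_pass"] = ~(per_target["cv"] > cv_max)

    # a sample is dropped entirely when any reference target fails its CV
    is_ref = per_target["target_id"].isin(reference_targets)
    ref_fail = (
        per_target[is_ref & ~per_target["cv_pass"]]
        .groupby(SAMPLE_KEY)
        .size()
        .rename("n_ref_cv_fail")
    )
    samples = per_target.groupby(SAMPLE_KEY).size().rename("n_targets").reset_index()
    samples = samples.merge(ref_fail.reset_index(), on=SAMPLE_KEY, how="left")
    samples["n_ref_cv_fail"] = samples["n_ref_cv_fail"].fillna(0).astype(int)
    samples["cv_refs_pass"] = samples["n_ref_cv_fail"] == 0

    # per-plate per-reference medians over CV-passing samples
    ref_rows = per_target[is_ref & per_target["cv_pass"]].merge(
        samples[SAMPLE_KEY + ["cv_refs_pass"]], on=SAMPLE_KEY
    )
    ref_rows = ref_rows[ref_rows["cv_refs_pass"]]
    ref_medians = (
        ref_rows.dropna(subset=["mean_ng"])
        .groupby(["plate_id", "target_id"])["mean_ng"]
        .median()
        .rename("plate_median")
    )

    # composite normalization constant per sample
    ref_rows = ref_rows.merge(
        ref_medians.reset_index(), on=["plate_id", "target_id"], how="left"
    )
    ref_rows["ratio"] = ref_rows["mean_ng"] / ref_rows["plate_median"]
    if (ref_rows["ratio"] <= 0).any():
        bad = ref_rows.loc[ref_rows["ratio"] <= 0].iloc[0]
        raise ValueError(
            f"nonpositive reference ratio for strain {bad.strain_id!r} "
            f"target {bad.target_id!r}"
        )

    def _cnorm(ratios: pd.Series) -> float:
        r = ratios.dropna().to_numpy()
        if r.size < min_refs:
            return float("nan")
        return _aggregate(r, method)

    cnorm = (
        ref_rows.groupby(SAMPLE_KEY)["ratio"].agg(_cnorm).rename("cnorm")
    )
    n_refs = (
        ref_rows.dropna(subset=["ratio"]).groupby(SAMPLE_KEY).size().rename("n_refs")
    )
    diagnostics = samples.merge(cnorm.reset_index(), on=SAMPLE_KEY, how="left")
    diagnostics = diagnostics.merge(n_refs.reset_index(), on=SAMPLE_KEY, how="left")
    diagnostics["n_refs"] = diagnostics["n_refs"].fillna(0).astype(int)
    diagnostics["log2_cnorm"] = np.log2(diagnostics["cnorm"])
    diagnostics["cnorm_pass"] = diagnostics["log2_cnorm"] >= log2_cnorm_min
    diagnostics["sample_pass"] = (
        diagnostics["cv_refs_pass"]
        & diagnostics["cnorm_pass"].fillna(False)
        & diagnostics["cnorm"].notna()
    )
    n_dropped = int((~diagnostics["sample_pass"]).sum())
    if n_dropped:
        logger.info("normalization dropped %d of %d samples", n_dropped, len(diagnostics))

    # measurement-level normalized and relative levels
    records = df.merge(
        per_target[SAMPLE_KEY + ["target_id", "cv", "cv_pass"]],
        on=SAMPLE_KEY + ["target_id"],
        how="left",
    )
    records = records.merge(
        diagnostics[SAMPLE_KEY + ["cnorm", "cnorm_pass", "sample_pass"]],
        on=SAMPLE_KEY,
        how="left",
    )
    include = (
        records["sample_pass"].fillna(False)
        & records["cv_pass"].fillna(False)
        & records["ng"].notna()
    )
    records["normalized_level"] = np.where(
        include, records["ng"] / records["cnorm"], np.nan
    )

    norm_medians = (
        records.dropna(subset=["normalized_level"])
        .groupby(["plate_id", "target_id"])["normalized_level"]
        .median()
        .rename("norm_median")
    )
    degenerate = norm_medians[~(norm_medians > 0)]
    for (plate, target), _ in degenerate.items():
        logger.warning(
            "plate %s target %s: nonpositive median of normalized levels; "
            "relative levels skipped",
            plate,
            target,
        )
    norm_medians = norm_medians[norm_medians > 0]
    records = records.merge(
        norm_medians.reset_index(), on=["plate_id", "target_id"], how="left"
    )
    records["rel"] = records["normalized_level"] / records["norm_median"]
    records = records.drop(columns=["norm_median"])

    diag_cols = SAMPLE_KEY + [
        "cnorm",
        "log2_cnorm",
        "n_refs",
        "cv_refs_pass",
        "cnorm_pass",
        "sample_pass",
    ]
    return records, diagnostics[diag_cols]


def rel_wide(records: pd.DataFrame, target_id: str) -> pd.DataFrame:
    """Pivot one target's Rel values to strains x replicate columns.

    Columns are named ``<bio_rep>_t<tech_rep>`` (e.g. A_t1, A_t2, B_t1,
    B_t2), mirroring the four independent measurements per strain.
    """
    sub = records[(records["target_id"] == target_id) & records["rel"].notna()]
    wide = sub.pivot_table(
        index="strain_id",
        columns=["bio_rep", "tech_rep"],
        values="rel",
        aggfunc="first",
    )
    wide.columns = [f"{b}_t{t}" for b, t in wide.columns]
    return wide


class ScreenNormalizer(TransformerMixin, BaseEstimator):
    """Estimator wrapper around :func:`normalize_screen`.

    ``fit`` evaluates the filters, per-plate medians and C_norm constants
    on a quantified screen; ``transform`` returns the measurement records
    with normalized and relative levels attached.
    """

    def __init__(
        self,
        reference_targets=(),
        cv_max: float = CV_MAX,
        log2_cnorm_min: float = LOG2_CNORM_MIN,
        min_refs: int = MIN_REFS,
        method: str = "geometric",
        strict_cv: bool = False,
    ):
        self.reference_targets = reference_targets
        self.cv_max = cv_max
        self.log2_cnorm_min = log2_cnorm_min
        self.min_refs = min_refs
        self.method = method
        self.strict_cv = strict_cv

    def fit(self, X: pd.DataFrame, y=None):
        records, diagnostics = normalize_screen(
            X,
            reference_targets=self.reference_targets,
            cv_max=self.cv_max,
            log2_cnorm_min=self.log2_cnorm_min,
            min_refs=self.min_refs,
            method=self.method,
            strict_cv=self.strict_cv,
        )
        self.records_ = records
        self.diagnostics_ = diagnostics
        self.n_samples_ = len(diagnostics)
        self.n_samples_passing_ = int(diagnostics["sample_pass"].sum())
        return self

    def transform(self, X=None) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "records_")
        return self.records_
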