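"""Quality filters, the composite normalization constant, and relative levels."""

import numpy as np
import pandas as pd
import pytest

import splicescreen as ss
from conftest import hand_plate

REFS = ["R1", "R2", "R3", "R4"]


class TestReplicateCV:
    def test_identical_replicates(self):
        assert ss.replicate_cv([5.0, 5.0]) == 0.0

    def test_hand_computed_sd_over_mean(self):
        # sd({1,2}) = 0.70711, mean 1.5 -> CV 0.4714, above the 0.25 cut
        cv = ss.replicate_cv([1.0, 2.0])
        assert cv == pytest.approx(np.sqrt(0.5) / 1.5, rel=1e-9)
        assert cv > 0.25

    def test_single_value_gives_missing_cv(self):
        assert np.isnan(ss.replicate_cv([3.0]))

    def test_zero_mean_raises(self):
        with pytest.raises(ValueError, match="zero mean"):
            ss.replicate_cv([1.0, -1.0])

    def test_threshold_is_strict(self):
        """A sample is excluded only when CV exceeds the threshold strictly:
        a CV exactly at the cut passes, one just above fails."""
        reps = [0.9, 1.1]
        vals = {
            (f"s{i}", "A"): {**{r: 1.0 for r in REFS}, "T": list(reps)}
            for i in range(5)
        }
        plate = hand_plate(vals, REFS + ["T"])
        first, _ = ss.normalize_screen(plate, REFS, cv_max=1.0)
        cv = first.loc[first["target_id"] == "T", "cv"].iloc[0]
        assert cv == pytest.approx(ss.replicate_cv(reps), rel=1e-12)
        for cv_max, should_pass in [(cv, True), (np.nextafter(cv, 0), False)]:
            records, _ = ss.normalize_screen(plate, REFS, cv_max=cv_max)
            t_rows = records[records["target_id"] == "T"]
            assert t_rows["cv_pass"].all() == should_pass


class TestPlateMedians:
    def test_odd_and_even_counts(self):
        df = pd.DataFrame(
            {
                "plate_id": ["P1"] * 5,
                "target_id": ["T"] * 3 + ["U"] * 2,
                "ng": [1.0, 2.0, 3.0, 1.0, 3.0],
            }
        )
        med = ss.plate_medians(df)
        assert med[("P1", "T")] == 2.0
        assert med[("P1", "U")] == 2.0  # midpoint convention

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(size=101)
        df = pd.DataFrame({"plate_id": "P1", "target_id": "T", "ng": vals})
        expected = np.sort(vals)[50]
        assert ss.plate_medians(df)[("P1", "T")] == expected


class TestComputeCnorm:
    MEDIANS = {f"R{i}": 1.0 for i in range(1, 7)}

    def test_sample_at_plate_medians(self):
        refs = {f"R{i}": 1.0 for i in range(1, 7)}
        assert ss.compute_cnorm(refs, self.MEDIANS) == pytest.approx(1.0)

    def test_uniform_four_fold_yield(self):
        refs = {f"R{i}": 4.0 for i in range(1, 7)}
        assert ss.compute_cnorm(refs, self.MEDIANS) == pytest.approx(4.0)

    def test_geometric_mean_of_mixed_ratios(self):
        ratios = [2, 2, 0.5, 1, 1, 1]
        refs = {f"R{i}": float(r) for i, r in enumerate(ratios, start=1)}
        assert ss.compute_cnorm(refs, self.MEDIANS) == pytest.approx(
            2 ** (1 / 6), rel=1e-12
        )

    def test_too_few_references_gives_missing(self):
        refs = {"R1": 1.0, "R2": 1.0, "R3": 1.0}
        assert np.isnan(ss.compute_cnorm(refs, self.MEDIANS, min_refs=4))

    def test_nonpositive_ratio_raises(self):
        refs = {f"R{i}": 1.0 for i in range(1, 7)}
        refs["R1"] = 0.0
        with pytest.raises(ValueError, match="nonpositive"):
            ss.compute_cnorm(refs, self.MEDIANS)

    def test_monotone_in_each_reference(self):
        refs = {f"R{i}": 1.0 for i in range(1, 7)}
        base = ss.compute_cnorm(refs, self.MEDIANS)
        refs["R3"] = 1.5
        assert ss.compute_cnorm(refs, self.MEDIANS) > base


class TestCnormFilter:
    @pytest.mark.parametrize(
        "cnorm,passes",
        [(1.0, True), (0.125, True), (0.124, False)],  # log2(0.125) = -3 exactly
    )
    def test_eight_fold_decrease_boundary(self, cnorm, passes):
        assert ss.apply_cnorm_filter(cnorm) is passes

    def test_nonpositive_cnorm_rejected(self):
        with pytest.raises(ValueError):
            ss.apply_cnorm_filter(0.0)


class TestRelativeLevels:
    def _plate(self, yields, target_extra=None):
        vals = {}
        for i, y in enumerate(yields):
            levels = {r: y for r in REFS}
            levels["T"] = y * (target_extra.get(i, 1.0) if target_extra else 1.0)
            vals[(f"s{i:02d}", "A")] = levels
        return hand_plate(vals, REFS + ["T"])

    def test_median_sample_has_rel_one(self):
        records, _ = ss.normalize_screen(self._plate([0.5, 0.8, 1.0, 1.3, 2.0]), REFS)
        mid = records[(records["strain_id"] == "s02") & (records["target_id"] == "T")]
        assert mid["rel"].to_numpy() == pytest.approx(1.0)

    def test_rel_median_is_one_per_plate_and_target(self, small_screen_results):
        records = small_screen_results["records"]
        med = (
            records.dropna(subset=["rel"])
            .groupby(["plate_id", "target_id"])["rel"]
            .median()
        )
        assert np.allclose(med, 1.0)

    def test_spreadsheet_oracle_on_hand_plate(self):
        """Step-by-step reimplementation with plain dict arithmetic."""
        yields = [0.6, 0.8, 0.9, 1.0, 1.1, 1.25, 1.5, 2.0]
        extra = {1: 3.0, 6: 0.5}
        plate = self._plate(yields, target_extra=extra)
        records, diag = ss.normalize_screen(plate, REFS)

        # independent oracle: medians -> ratios -> cnorm -> normalized -> rel
        by_sample = {
            f"s{i:02d}": {**{r: y for r in REFS}, "T": y * extra.get(i, 1.0)}
            for i, y in enumerate(yields)
        }
        medians = {
            t: float(np.median([v[t] for v in by_sample.values()]))
            for t in REFS + ["T"]
        }
        cnorms = {
            s: float(np.prod([v[r] / medians[r] for r in REFS]) ** (1 / len(REFS)))
            for s, v in by_sample.items()
        }
        normalized = {s: v["T"] / cnorms[s] for s, v in by_sample.items()}
        t_median = float(np.median(list(normalized.values())))
        expected_rel = {s: n / t_median for s, n in normalized.items()}

        got = (
            records[records["target_id"] == "T"]
            .groupby("strain_id")["rel"]
            .first()
        )
        for s, exp in expected_rel.items():
            assert got[s] == pytest.approx(exp, rel=1e-12)
        for s, cn in cnorms.items():
            row = diag[diag["strain_id"] == s]
            assert row["cnorm"].iloc[0] == pytest.approx(cn, rel=1e-12)

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.0, 100.0])
    def test_single_sample_yield_invariance(self, c):
        """Scaling every measurement of one sample leaves all Rel unchanged."""
        yields = [0.6, 0.8, 0.9, 1.0, 1.1, 1.25, 1.5, 2.0]
        plate = self._plate(yields, target_extra={3: 1.7})
        base, _ = ss.normalize_screen(plate, REFS)
        scaled_plate = plate.copy()
        mask = scaled_plate["strain_id"] == "s07"  # yield 2: stays above filter at c=0.1
        scaled_plate.loc[mask, "ng"] *= c
        scaled, _ = ss.normalize_screen(scaled_plate, REFS)
        assert np.allclose(
            base["rel"].to_numpy(), scaled["rel"].to_numpy(), rtol=1e-9, equal_nan=True
        )

    def test_failing_sample_keeps_flags_but_no_levels(self):
        yields = [0.5, 0.9, 1.0, 1.1, 2.0]
        plate = self._plate(yields)
        # crash one sample's yield far below the 8-fold C_norm cut
        plate.loc[plate["strain_id"] == "s00", "ng"] *= 0.01
        records, diag = ss.normalize_screen(plate, REFS)
        failed = diag[diag["strain_id"] == "s00"]
        assert not failed["cnorm_pass"].iloc[0]
        rows = records[records["strain_id"] == "s00"]
        assert rows["rel"].isna().all()
        assert rows["cnorm_pass"].eq(False).all()

    def test_cnorm_correlates_with_injected_yields(self, small_screen, small_screen_results):
        diag = small_screen_results["diagnostics"]
        truth = small_screen.strain_truth.set_index("strain_id")
        merged = diag.merge(
            truth[["yield_A", "yield_B"]], left_on="strain_id", right_index=True
        )
        injected = np.where(
            merged["bio_rep"] == "A", merged["yield_A"], merged["yield_B"]
        )
        r = np.corrcoef(np.log2(injected), merged["log2_cnorm"])[0, 1]
        assert r >= 0.99
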