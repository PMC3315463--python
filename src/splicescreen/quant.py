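"""Standard-curve quantification of QPCR crossing points.

A standard curve is the least-squares line of Cp against log10(known
template quantity); its slope gives the per-cycle amplification efficiency

    E = 10**(-1/slope) - 1

so a perfect doubling per cycle corresponds to slope -1/log10(2) = -3.3219
and E = 1 (100%).  Quantities recovered through a curve are relative
(genomic-DNA-equivalent nanograms), never absolute copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class StandardCurveModel(RegressorMixin, BaseEstimator):
    """Log-linear Cp-versus-quantity calibration model.

    Fit with known dilution-series points; ``predict`` maps quantities to
    expected Cp, ``quantity`` inverts a measured Cp back to a relative
    quantity.

    Attributes
    ----------
    slope_ : float
        Cycles per log10 quantity (negative for a valid dilution series).
    intercept_ : float
        Cp at quantity 1.
    r_squared_ : float
        Coefficient of determination of the fit.
    efficiency_ : float
        Amplification efficiency ``10**(-1/slope_) - 1``.
    """

    def __init__(self, target_id: str | None = None):
        self.target_id = target_id

    def fit(self, quantity, cp=None):
        """Fit the curve from known quantities and measured Cp values.

        Parameters
        ----------
        quantity : array-like of shape (n_points,), all > 0
        cp : array-like of shape (n_points,)
        """
        q = np.asarray(quantity, dtype=float).ravel()
        y = np.asarray(cp, dtype=float).ravel()
        if q.shape != y.shape:
            raise ValueError("quantity and cp must have the same length")
        if q.size < 3:
            raise ValueError(f"need >= 3 dilution points, got {q.size}")
        if np.any(q <= 0):
            raise ValueError("known quantities must be strictly positive")
        if np.unique(q).size < 2:
            raise ValueError("degenerate dilution series: a single distinct quantity")
        res = stats.linregress(np.log10(q), y)
        if res.slope >= 0:
            raise ValueError(
                f"fitted slope {res.slope:.4g} is non-negative: invalid dilution "
                "series (Cp must decrease with template amount)"
            )
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.efficiency_ = float(10.0 ** (-1.0 / self.slope_) - 1.0)
        self.n_points_ = int(q.size)
        return self

    @classmethod
    def from_parameters(cls, slope: float, intercept: float, target_id=None):
        """Build an already-calibrated curve from (slope, intercept)."""
        if slope >= 0:
            raise ValueError("slope must be negative")
        model = cls(target_id=target_id)
        model.slope_ = float(slope)
        model.intercept_ = float(intercept)
        model.r_squared_ = float("nan")
        model.efficiency_ = float(10.0 ** (-1.0 / slope) - 1.0)
        model.n_points_ = 0
        return model

    def predict(self, quantity):
        """Expected Cp for given quantities (the fitted line)."""
        check_is_fitted(self, "slope_")
        q = np.asarray(quantity, dtype=float)
        return self.slope_ * np.log10(q) + self.intercept_

    def quantity(self, cp):
        """Invert measured Cp values to relative quantities.

        Missing (NaN) Cp propagates to a missing quantity.
        """
        check_is_fitted(self, "slope_")
        cp = np.asarray(cp, dtype=float)
        return 10.0 ** ((cp - self.intercept_) / self.slope_)


@dataclass(frozen=True)
class StandardCurve:
    """Frozen view of a fitted curve (slope, intercept, r^2, efficiency)."""

    target_id: str | None
    slope: float
    intercept: float
    r_squared: float
    efficiency: float


def fit_standard_curve(points) -> StandardCurveModel:
    """Fit a standard curve from (known_quantity, cp) pairs.

    *points* is any iterable of 2-tuples, or a DataFrame with
    ``known_quantity`` and ``cp`` columns.
    """
    if isinstance(points, pd.DataFrame):
        q, cp = points["known_quantity"], points["cp"]
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (known_quantity, cp) pairs")
        q, cp = arr[:, 0], arr[:, 1]
    return StandardCurveModel().fit(q, cp)


def cp_to_quantity(cp, curve: StandardCurveModel):
    """Convert Cp to relative quantity through a fitted curve."""
    return curve.quantity(cp)


def fit_curves(curve_points: pd.DataFrame) -> dict:
    """Fit one StandardCurveModel per target from a tidy dilution table.

    Expects columns target_id, known_quantity, cp.
    """
    curves = {}
    for target, grp in curve_points.groupby("target_id"):
        model = StandardCurveModel(target_id=target).fit(grp["known_quantity"], grp["cp"])
        curves[target] = model
    return curves


def quantify(cp_table: pd.DataFrame, curves: dict) -> pd.DataFrame:
    """Add an ``ng`` column of relative quantities to a Cp record table.

    Every target in *cp_table* must have a curve; missing Cp yields
    missing ng.
    """
    missing = sorted(set(cp_table["target_id"]) - set(curves))
    if missing:
        raise ValueError(f"no standard curve for targets: {missing}")
    out = cp_table.copy()
    ng = np.empty(len(out))
    for target, grp in out.groupby("target_id"):
        ng[out.index.get_indexer(grp.index)] = curves[target].quantity(grp["cp"])
    out["ng"] = ng
    return out


def chip_fold_enrichment(ip_pct, mock_pct, ref_ip_pct, ref_mock_pct):
    """Mock-subtracted percent-input signal relative to a control locus.

    Returns (ip - mock) / (ref_ip - ref_mock); the reference difference is
    the same statistic at an intronless control region and must be nonzero.
    """
    ref_diff = ref_ip_pct - ref_mock_pct
    if ref_diff == 0:
        raise ValueError(
            "reference region has zero mock-subtracted signal: "
            "uninformative control locus"
        )
    return (ip_pct - mock_pct) / ref_diff
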