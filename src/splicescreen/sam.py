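"""One-class Significance Analysis of Microarrays (SAM) for screen data.

The screen measures one RNA species in thousands of mutant strains, each
with a handful of replicate values (log2 relative levels).  SAM treats
each strain like a gene in a microarray experiment: the moderated
statistic

    d_i = (mean_i - mu0) / (se_i + s0)

shrinks the influence of strains whose tiny standard errors would
otherwise dominate, with the fudge factor s0 chosen from percentiles of
the standard-error distribution so that the spread of d is as uniform as
possible across the se range.  A sign-flip permutation null provides the
expected order statistics d-bar_(i); strains whose observed d departs from
its expected order statistic by more than a threshold Delta are called
significant, and the false discovery rate is estimated from the median
number of permuted statistics falling beyond the calling cuts.

Permutations flip one random sign vector per permutation across the
replicate columns, applied to every strain's deviations from mu0 (the
scheme of the original SAM program for one-class data).  With n replicate
columns there are only 2**n distinct sign vectors, so for n <= 12 the null
is enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

S0_PERCENTILES = np.arange(0, 101, 5)
EXHAUSTIVE_MAX_REPS = 12


def compute_d(values, mu0: float = 0.0, s0: float = 0.0):
    """SAM d statistic for one strain's replicate values.

    d = (mean - mu0) / (se + s0) with se the standard error of the mean.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    if v.shape[1] < 2:
        raise ValueError("need >= 2 replicate values per strain")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    mean = v.mean(axis=1)
    se = v.std(axis=1, ddof=1) / np.sqrt(v.shape[1])
    d = (mean - mu0) / (se + s0)
    return float(d[0]) if np.asarray(values).ndim == 1 else d


def estimate_s0(means, ses) -> float:
    """Choose the fudge factor s0 by the standard SAM percentile criterion.

    Candidates are the percentiles {0, 5, ..., 100} of the se
    distribution.  For each candidate, strains are windowed by se
    quantiles; the candidate minimizing the coefficient of variation of
    the within-window median absolute deviations of d is selected, ties
    broken toward the smallest candidate.
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    n = means.size
    if n < 20:
        warnings.warn(
            f"s0 estimated from only {n} strains; the percentile criterion "
            "is unstable below ~20",
            stacklevel=2,
        )
    candidates = np.percentile(ses, S0_PERCENTILES)
    if np.all(ses == 0):
        warnings.warn("all standard errors are zero; using smallest positive s0 candidate", stacklevel=2)
        return float(np.finfo(float).tiny)
    cvs = np.array([_s0_criterion(means, ses, s0) for s0 in candidates])
    best = int(np.nanargmin(np.where(np.isnan(cvs), np.inf, cvs)))
    # tie toward the smallest candidate value
    tol = 1e-12
    for i in np.argsort(candidates, kind="stable"):
        if cvs[i] <= cvs[best] + tol:
            best = int(i)
            break
    return float(candidates[best])


def _s0_criterion(means, ses, s0, n_windows: int = 100):
    """Coefficient of variation of windowed MADs of d at a candidate s0."""
    d = means / (ses + s0)
    n = means.size
    n_windows = min(n_windows, max(2, n // 5))
    edges = np.percentile(ses, np.linspace(0, 100, n_windows + 1))
    idx = np.searchsorted(edges, ses, side="right") - 1
    idx = np.clip(idx, 0, n_windows - 1)
    mads = []
    for w in range(n_windows):
        dw = d[idx == w]
        if dw.size:
            med = np.median(dw)
            mads.append(np.median(np.abs(dw - med)) * 1.4826)
    mads = np.asarray(mads)
    if mads.size < 2 or np.mean(mads) == 0:
        return np.nan
    return float(np.std(mads, ddof=1) / np.mean(mads))


def sign_vectors(n_reps: int) -> np.ndarray:
    """All 2**n_reps sign assignments over the replicate columns."""
    return np.array(list(itertools.product((1.0, -1.0), repeat=n_reps)))


class OneClassSAM(BaseEstimator):
    """One-class SAM over strains x replicates data.

    Parameters
    ----------
    mu0 : float
        Null reference value (0 in log2 relative-level space).
    s0 : float or None
        Fudge factor; estimated by the SAM percentile criterion when None.
    delta : float or None
        Calling threshold on |d - dbar|; when None, the Delta minimizing
        the estimated FDR subject to at least one call is chosen from the
        sweep (ties toward the smallest Delta, i.e. the most calls).
    n_permutations : int
        Number of sampled sign-flip permutations; ignored when the null is
        enumerated exhaustively.
    exhaustive : bool or 'auto'
        Enumerate all 2**n_reps sign vectors when n_reps <= 12 ('auto' or
        True); sample otherwise.
    random_state : int
        Seed for the sampled permutation null.

    Attributes
    ----------
    d_ : ndarray of shape (n_strains,), observed statistics in input order.
    dbar_ : ndarray, permutation expected order statistics aligned with
        ``order_`` (ascending d).
    order_ : ndarray, indices sorting strains by ascending d (ties broken
        by strain label).
    s0_, delta_, fdr_ : chosen operating point.
    calls_ : ndarray of {'positive', 'negative', 'none'} in input order.
    sweep_ : DataFrame with columns delta, n_called, n_positive,
        n_negative, fdr.
    """

    def __init__(
        self,
        mu0: float = 0.0,
        s0: float | None = None,
        delta: float | None = None,
        n_permutations: int = 1000,
        exhaustive: bool | str = "auto",
        random_state: int = 0,
    ):
        self.mu0 = mu0
        self.s0 = s0
        self.delta = delta
        self.n_permutations = n_permutations
        self.exhaustive = exhaustive
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the SAM model on strains x replicates values (log2 Rel)."""
        labels = None
        if isinstance(X, pd.DataFrame):
            labels = X.index.to_numpy()
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be 2-D with >= 2 replicate columns")
        if not np.isfinite(X).all():
            raise ValueError("X must be finite; drop incomplete strains first")
        n_strains, n_reps = X.shape
        if labels is None:
            labels = np.arange(n_strains)
        self.strain_labels_ = labels

        dev = X - self.mu0
        means = dev.mean(axis=1)
        ses = dev.std(axis=1, ddof=1) / np.sqrt(n_reps)
        self.s0_ = float(self.s0) if self.s0 is not None else estimate_s0(means, ses)
        self.d_ = means / (ses + self.s0_)

        # ascending d with deterministic label tie-break
        self.order_ = np.lexsort((labels, self.d_))
        self.d_sorted_ = self.d_[self.order_]

        self.perm_d_, self.exhaustive_ = self._permutation_d(dev)
        self.perm_d_sorted_ = np.sort(self.perm_d_, axis=1)
        self.dbar_ = self.perm_d_sorted_.mean(axis=0)
        self.n_permutations_ = self.perm_d_.shape[0]

        self.sweep_ = self.delta_sweep()
        if self.delta is not None:
            self.delta_ = float(self.delta)
        else:
            self.delta_ = self._fdr_minimizing_delta(self.sweep_)
        calls, fdr, n_called = self._call(self.delta_)
        self.calls_ = calls
        self.fdr_ = fdr
        self.n_called_ = n_called
        self.no_calls_ = n_called == 0
        return self

    def _permutation_d(self, dev: np.ndarray) -> tuple[np.ndarray, bool]:
        """d statistics under sign-flip permutations (rows: permutations)."""
        n_strains, n_reps = dev.shape
        exhaustive = self.exhaustive
        if exhaustive == "auto":
            exhaustive = n_reps <= EXHAUSTIVE_MAX_REPS
        if exhaustive:
            signs = sign_vectors(n_reps)
        else:
            rng = np.random.default_rng(self.random_state)
            signs = rng.choice((1.0, -1.0), size=(int(self.n_permutations), n_reps))
        sqrt_n = np.sqrt(n_reps)
        perm_d = np.empty((signs.shape[0], n_strains))
        for b, s in enumerate(signs):
            flipped = dev * s
            m = flipped.mean(axis=1)
            se = flipped.std(axis=1, ddof=1) / sqrt_n
            perm_d[b] = m / (se + self.s0_)
        return perm_d, bool(exhaustive)

    # -- calling and FDR ---------------------------------------------------

    def _cuts(self, delta: float):
        """Calling cuts (cut_low, cut_up) on the d scale for a given Delta.

        Walking up from the smallest positive-d rank, the first strain with
        d - dbar >= Delta sets cut_up; the mirror rule walking down over
        the negative side sets cut_low.
        """
        d, dbar = self.d_sorted_, self.dbar_
        diff = d - dbar
        cut_up = np.inf
        pos = np.nonzero(d >= 0)[0]
        exceed = pos[diff[pos] >= delta]
        if exceed.size:
            cut_up = d[exceed[0]]
        cut_low = -np.inf
        neg = np.nonzero(d <= 0)[0][::-1]
        exceed = neg[-diff[neg] >= delta]
        if exceed.size:
            cut_low = d[exceed[0]]
        return cut_low, cut_up

    def _call(self, delta: float):
        cut_low, cut_up = self._cuts(delta)
        calls = np.full(self.d_.shape, "none", dtype=object)
        calls[self.d_ >= cut_up] = "positive"
        calls[self.d_ <= cut_low] = "negative"
        n_called = int((calls != "none").sum())
        fdr = self._fdr(cut_low, cut_up, n_called)
        return calls, fdr, n_called

    def _exceedance_counts(self, cut_low, cut_up) -> np.ndarray:
        """Per-permutation counts of permuted d beyond the calling cuts.

        Accepts scalar cuts or aligned arrays of cuts; returns an array of
        shape (n_permutations,) or (n_permutations, n_cuts).
        """
        cut_low = np.atleast_1d(np.asarray(cut_low, dtype=float))
        cut_up = np.atleast_1d(np.asarray(cut_up, dtype=float))
        sp = self.perm_d_sorted_
        n = sp.shape[1]
        counts = np.empty((sp.shape[0], cut_up.size))
        for b in range(sp.shape[0]):
            up = n - np.searchsorted(sp[b], cut_up, side="left")
            low = np.searchsorted(sp[b], cut_low, side="right")
            counts[b] = up + low
        return counts

    def _fdr(self, cut_low: float, cut_up: float, n_called: int) -> float:
        """Median permuted exceedance count over the number called, capped at 1."""
        if n_called == 0:
            return 0.0
        counts = self._exceedance_counts(cut_low, cut_up)[:, 0]
        return float(min(1.0, np.median(counts) / n_called))

    def delta_sweep(self, deltas=None) -> pd.DataFrame:
        """Evaluate calls and FDR over a grid of Delta values.

        By default the grid is the set of attainable thresholds: the unique
        nonnegative values of |d - dbar| (plus 0), capped at 512 points by
        quantile thinning for very large screens.
        """
        check_is_fitted(self, "dbar_")
        if deltas is None:
            diffs = np.abs(self.d_sorted_ - self.dbar_)
            deltas = np.unique(np.concatenate(([0.0], diffs)))
            if deltas.size > 512:
                deltas = np.unique(
                    np.percentile(deltas, np.linspace(0, 100, 512))
                )
        deltas = np.asarray(deltas, dtype=float)
        cuts = np.array([self._cuts(delta) for delta in deltas])
        cut_low, cut_up = cuts[:, 0], cuts[:, 1]
        n_pos = (self.d_sorted_[:, None] >= cut_up[None, :]).sum(axis=0)
        n_neg = (self.d_sorted_[:, None] <= cut_low[None, :]).sum(axis=0)
        n_called = n_pos + n_neg
        med_counts = np.median(self._exceedance_counts(cut_low, cut_up), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.minimum(1.0, med_counts / n_called)
        fdr = np.where(n_called == 0, 0.0, fdr)
        return pd.DataFrame(
            {
                "delta": deltas,
                "n_called": n_called.astype(int),
                "n_positive": n_pos.astype(int),
                "n_negative": n_neg.astype(int),
                "fdr": fdr,
            }
        )

    @staticmethod
    def _fdr_minimizing_delta(sweep: pd.DataFrame) -> float:
        """Delta minimizing FDR subject to >= 1 call; ties to smallest Delta."""
        callable_rows = sweep[sweep["n_called"] >= 1]
        if callable_rows.empty:
            return float(sweep["delta"].iloc[0]) if len(sweep) else 0.0
        best_fdr = callable_rows["fdr"].min()
        ties = callable_rows[callable_rows["fdr"] <= best_fdr + 1e-15]
        return float(ties["delta"].iloc[0])

    # -- results -----------------------------------------------------------

    def result_table(self) -> pd.DataFrame:
        """Per-strain SAM table: d, expected order statistic, call."""
        check_is_fitted(self, "calls_")
        dbar_in_input_order = np.empty_like(self.dbar_)
        dbar_in_input_order[self.order_] = self.dbar_
        return pd.DataFrame(
            {
                "strain_id": self.strain_labels_,
                "d": self.d_,
                "dbar": dbar_in_input_order,
                "call": self.calls_,
            }
        )

    def predict(self, X=None) -> np.ndarray:
        """Significance calls for the fitted strains."""
        check_is_fitted(self, "calls_")
        return self.calls_


def sam_analysis(
    values: pd.DataFrame,
    mu0: float = 0.0,
    delta: float | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> OneClassSAM:
    """Run one-class SAM on a strains x replicates table of log2 Rel values.

    Strains with any missing replicate are dropped (with a logged count),
    matching the screen's use of the four complete measurements per strain.
    """
    complete = values.dropna()
    n_dropped = len(values) - len(complete)
    if n_dropped:
        logger.info(
            "SAM: dropped %d of %d strains lacking the full replicate complement",
            n_dropped,
            len(values),
        )
    model = OneClassSAM(
        mu0=mu0, delta=delta, n_permutations=n_permutations, random_state=seed
    )
    return model.fit(complete)
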