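"""Screen-level synthesis: rank aggregation, splicing efficiency, and
gene-set enrichment of top candidates.

Each strain is summarized per precursor transcript by the mean of its
log2 relative levels; ranking those summaries (1 = strongest precursor
accumulation) per transcript and averaging the ranks over the canonical
splicing substrates gives a composite rank order that is robust to
transcript-specific effects.  Over-representation of an annotated gene
set (for example the known splicing factors) among the top-N strains is
scored with the one-sided Fisher exact / hypergeometric tail, computed in
log space so that p-values far below double underflow of individual terms
(down to ~1e-300) remain exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

DEFAULT_TOP_NS = (50, 100, 200)


def rank_strains(values: pd.Series) -> pd.Series:
    """Descending ranks of per-strain summaries (1 = highest level).

    Ties receive average ranks.  Missing summaries are excluded.
    """
    v = values.dropna()
    return v.rank(ascending=False, method="average")


def composite_rank(ranks: pd.DataFrame, min_targets: int = 3) -> pd.DataFrame:
    """Average per-target ranks into a composite per-strain rank.

    Parameters
    ----------
    ranks : DataFrame, strains x targets of per-target ranks.
    min_targets : strains with ranks for fewer targets are flagged
        (``enough_targets`` False) and placed last.

    Returns a DataFrame with ``composite_rank``, ``n_targets`` and
    ``enough_targets`` columns, sorted best-first.
    """
    n_targets = ranks.notna().sum(axis=1)
    composite = ranks.mean(axis=1)
    out = pd.DataFrame(
        {
            "composite_rank": composite,
            "n_targets": n_targets,
            "enough_targets": n_targets >= min_targets,
        }
    )
    # flagged strains sort after every ranked strain
    sort_key = out["composite_rank"].where(out["enough_targets"], np.inf)
    return out.loc[sort_key.sort_values(kind="stable").index]


def splicing_efficiency(rel_precursor, rel_total):
    """Unspliced:spliced index: relative precursor over relative total.

    Higher values mean worse splicing.  A nonpositive or missing total
    yields a missing value with a logged warning.
    """
    prec = np.asarray(rel_precursor, dtype=float)
    total = np.asarray(rel_total, dtype=float)
    bad = ~(total > 0)
    if bad.any():
        logger.warning(
            "splicing efficiency undefined for %d strains with nonpositive "
            "total RNA level",
            int(bad.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, prec / total)
    return float(out) if np.ndim(rel_precursor) == 0 else out


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided hypergeometric over-representation test result."""

    N: int  # background size
    K: int  # annotated strains in the background
    n: int  # top-list size
    k: int  # annotated strains in the top list
    p: float  # upper-tail probability P(X >= k)


def _log_hypergeom_pmf(i, N, K, n):
    """log C(K,i) + log C(N-K,n-i) - log C(N,n) via log-gamma."""
    i = np.asarray(i, dtype=float)

    def logcomb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logcomb(K, i) + logcomb(N - K, n - i) - logcomb(N, n)


def hypergeom_tail(N: int, K: int, n: int, k) -> np.ndarray:
    """Upper-tail P(X >= k) of Hypergeometric(N, K, n), in log space.

    Vectorized over k.  Exact down to ~1e-300.
    """
    k = np.atleast_1d(np.asarray(k, dtype=int))
    hi = min(K, n)
    support = np.arange(0, hi + 1)
    logpmf = _log_hypergeom_pmf(support, N, K, n)
    # suffix log-sum-exp: log P(X >= i) for every i in the support
    logtail = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    kk = np.clip(k, 0, hi)
    out = np.exp(logtail[kk])
    out[k <= 0] = 1.0
    out[k > hi] = 0.0
    return np.minimum(out, 1.0)


def enrichment_test(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """One-sided Fisher exact test for over-representation.

    P(X >= k) with X ~ Hypergeometric(N, K, n): the chance that a random
    top list of size n from N background strains contains at least k of
    the K annotated strains.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N and k >= 0):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    p = float(hypergeom_tail(N, K, n, k)[0])
    p = min(1.0, max(p, 0.0))
    return EnrichmentResult(N=N, K=K, n=n, k=k, p=p)


def gene_set_enrichment(
    ordered_strains,
    gene_sets: dict,
    top_ns=DEFAULT_TOP_NS,
    background=None,
) -> pd.DataFrame:
    """Enrichment of each gene set among the top-N of an ordered strain list.

    Parameters
    ----------
    ordered_strains : sequence of strain ids, best candidate first.
    gene_sets : mapping set name -> collection of strain ids.
    top_ns : cutoffs at which to evaluate the top list.
    background : optional collection defining the background population;
        defaults to the ordered list itself (strains passing all filters).

    Returns a tidy table with raw p and Bonferroni-adjusted p (adjusted
    across gene sets within each cutoff); raw p is primary.
    """
    ordered = list(ordered_strains)
    bg = set(background) if background is not None else set(ordered)
    n_sets = len(gene_sets)
    rows = []
    for top_n in top_ns:
        top = [s for s in ordered[:top_n] if s in bg]
        for name, members in gene_sets.items():
            members = set(members) & bg
            if not members:
                logger.warning("gene set %r has no members in background; skipped", name)
                continue
            k = len(members.intersection(top))
            res = enrichment_test(len(bg), len(members), len(top), k)
            rows.append(
                {
                    "gene_set": name,
                    "top_n": top_n,
                    "N": res.N,
                    "K": res.K,
                    "n": res.n,
                    "k": res.k,
                    "p": res.p,
                    "p_bonferroni": min(1.0, res.p * n_sets),
                }
            )
    return pd.DataFrame(rows)


def plot_ordered_rel(summary: pd.Series, members=None, ax=None, log2: bool = True):
    """Plot per-strain relative levels ordered high to low, highlighting a
    gene set's members (the screen's classic overview figure).

    Parameters
    ----------
    summary : Series indexed by strain_id (linear Rel summaries).
    members : optional collection of strain ids to highlight.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ordered = summary.dropna().sort_values(ascending=False)
    y = np.log2(ordered) if log2 else ordered
    x = np.arange(1, len(ordered) + 1)
    ax.scatter(x, y, s=4, c="0.6", label="all strains")
    if members:
        mask = ordered.index.isin(set(members))
        ax.scatter(x[mask], y[mask], s=8, c="crimson", label="gene set")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("strain rank")
    ax.set_ylabel("log2 relative level" if log2 else "relative level")
    return ax


def candidate_report(
    sam_tables: dict,
    composite: pd.DataFrame | None = None,
    gene_sets: dict | None = None,
    top_ns=DEFAULT_TOP_NS,
) -> dict:
    """Join per-target SAM calls into a candidate table with enrichment.

    Parameters
    ----------
    sam_tables : mapping target_id -> per-strain SAM result table
        (columns strain_id, d, call), one per analyzed precursor.
    composite : optional output of :func:`composite_rank`.
    gene_sets : optional mapping of set name -> members; enrichment is
        evaluated on strains ordered by decreasing maximal d.

    Returns
    -------
    dict with ``candidates`` (strains significant for >= 1 target, ordered
    by decreasing maximal d, with per-target calls) and ``enrichment``
    (may be empty when no gene sets are supplied).
    """
    if not sam_tables:
        raise ValueError("need SAM results for at least one target")
    calls = {}
    dmax = {}
    for target, table in sam_tables.items():
        t = table.set_index("strain_id")
        calls[target] = t["call"]
        dmax[target] = t["d"]
    call_df = pd.DataFrame(calls).fillna("none")
    d_df = pd.DataFrame(dmax)
    report = pd.DataFrame(
        {
            "max_d": d_df.max(axis=1),
            "n_significant_targets": (call_df != "none").sum(axis=1),
        }
    )
    report = report.join(call_df.add_prefix("call_"))
    if composite is not None:
        report = report.join(composite["composite_rank"])
    if gene_sets:
        for name, members in gene_sets.items():
            report[f"in_{name}"] = report.index.isin(set(members))
    report = report.sort_values("max_d", ascending=False, kind="stable")
    candidates = report[report["n_significant_targets"] > 0]

    enrichment = pd.DataFrame()
    if gene_sets:
        enrichment = gene_set_enrichment(
            report.index.to_list(), gene_sets, top_ns=top_ns
        )
    elif gene_sets is not None:
        logger.warning("empty gene sets: enrichment skipped")
    return {"candidates": candidates, "report": report, "enrichment": enrichment}
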