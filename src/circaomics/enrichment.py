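"""Set-level statistics: rhythmic-set overlaps, over-representation
analysis and phase histograms.

Overlap between two rhythmic sets drawn from a shared universe is tested
with Fisher's exact test on the 2x2 incidence table (used, e.g., to compare
detections across methods or temperatures).  Over-representation of
annotation terms in a feature set uses the hypergeometric upper tail with
Benjamini-Hochberg correction across terms; the universe defaults to the
features the detection was actually attempted on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSet:
    """A labelled feature set inside a finite universe."""

    label: str
    members: frozenset
    universe_size: int

    def __post_init__(self) -> None:
        if len(self.members) > self.universe_size:
            raise ValueError("set larger than its universe")

    @classmethod
    def from_ids(cls, label: str, ids, universe_size: int) -> "FeatureSet":
        return cls(label, frozenset(ids), universe_size)


def overlap_fisher(
    set_a: FeatureSet, set_b: FeatureSet, alternative: str = "two-sided"
) -> dict:
    """Fisher's exact test of overlap between two sets in one universe.

    The 2x2 table counts (in both, A only, B only, neither); ``greater``
    gives the one-sided enrichment test.  The odds ratio may be infinite.
    """
    if set_a.universe_size != set_b.universe_size:
        raise ValueError("sets live in different universes")
    n = set_a.universe_size
    both = len(set_a.members & set_b.members)
    a_only = len(set_a.members) - both
    b_only = len(set_b.members) - both
    neither = n - both - a_only - b_only
    if neither < 0:
        raise ValueError("universe smaller than the union of the sets")
    table = [[both, a_only], [b_only, neither]]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return {
        "n_overlap": both,
        "table": table,
        "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
        "p_value": float(p),
        "alternative": alternative,
    }


def overlap_threshold_sweep(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    thresholds,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Overlap of rhythmic sets as the adjusted-p threshold is relaxed.

    At each threshold the rhythmic sets are re-formed from both result
    tables (adj_p < threshold) and tested with Fisher's exact test; the
    overlap fraction is relative to the smaller set.  The threshold grid
    must be strictly increasing.
    """
    thr = np.asarray(list(thresholds), dtype=float)
    if np.any(np.diff(thr) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    shared = results_a.index.intersection(results_b.index)
    if len(shared) == 0:
        raise ValueError("result tables share no features")
    a = results_a.loc[shared]
    b = results_b.loc[shared]
    rows = []
    for t in thr:
        sa = FeatureSet.from_ids("A", a.index[a["adj_p"] < t], len(shared))
        sb = FeatureSet.from_ids("B", b.index[b["adj_p"] < t], len(shared))
        denom = min(len(sa.members), len(sb.members))
        if denom == 0:
            rows.append({"threshold": t, "n_a": len(sa.members),
                         "n_b": len(sb.members), "n_overlap": 0,
                         "overlap_fraction": 0.0, "p_value": 1.0,
                         "note": "empty set"})
            continue
        res = overlap_fisher(sa, sb, alternative)
        rows.append({
            "threshold": t, "n_a": len(sa.members), "n_b": len(sb.members),
            "n_overlap": res["n_overlap"],
            "overlap_fraction": res["n_overlap"] / denom,
            "p_value": res["p_value"], "note": "",
        })
    return pd.DataFrame(rows)


def ora_enrichment(
    foreground: FeatureSet,
    annotations: pd.DataFrame,
    universe_ids=None,
    min_hits: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms.

    ``annotations`` has columns (term_id, member_id) and optionally
    term_name.  When ``universe_ids`` is given the annotation is restricted
    to it (and the foreground must be contained in it); otherwise the
    universe size of the foreground set is used with the annotation taken
    at face value.  Terms with fewer than ``min_hits`` foreground hits are
    excluded; p-values are BH-adjusted across the tested terms.
    """
    if annotations.empty:
        raise ValueError("empty annotation table")
    ann = annotations.drop_duplicates(["term_id", "member_id"])
    if universe_ids is not None:
        universe = set(universe_ids)
        if not set(foreground.members) <= universe:
            raise ValueError("foreground not contained in the universe")
        ann = ann[ann["member_id"].isin(universe)]
        n_universe = len(universe)
    else:
        n_universe = foreground.universe_size
    fg = set(foreground.members)
    n_fg = len(fg)
    rows = []
    for term_id, grp in ann.groupby("term_id"):
        members = set(grp["member_id"])
        k = len(members & fg)
        if k < min_hits:
            continue
        m = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_universe, m, n_fg))
        row = {"term_id": term_id, "n_term": m, "n_hits": k, "p_value": p}
        if "term_name" in grp.columns:
            row["term_name"] = grp["term_name"].iloc[0]
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        logger.warning("no term reached %d foreground hits", min_hits)
        return out
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def phase_histogram(
    results: pd.DataFrame, bin_h: float = 3.0, period_h: float = 24.0
) -> pd.Series:
    """Counts of rhythmic features per peak-phase bin over [0, period).

    The bin width must divide the period; the total equals the number of
    rhythmic features.
    """
    n_bins = period_h / bin_h
    if not np.isclose(n_bins, round(n_bins)):
        raise ValueError("bin width must divide the period")
    phases = results.loc[results["rhythmic"], "phase_h"].to_numpy(dtype=float)
    if phases.size == 0:
        raise ValueError("no rhythmic features to histogram")
    edges = bin_h * np.arange(int(round(n_bins)) + 1)
    counts, _ = np.histogram(phases % period_h, bins=edges)
    return pd.Series(counts, index=edges[:-1], name="count")
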