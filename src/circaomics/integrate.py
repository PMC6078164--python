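"""Cross-layer integration: RNA-protein pairing, correlation structure,
phase lags, cross-correlation, PCA trajectories, enzyme-metabolite matching.

Pairing is protein-centric: each protein keeps at most one transcript (the
most rhythmic candidate).  Pair correlations are Pearson coefficients of
replicate-averaged temporal profiles over a shared circadian window
(CT30-CT81 by default, the proteomics span), on detrended profiles by
default since shared 24-h structure is what the correlation is probing.
Enzyme-metabolite integration crosses a protein -> EC -> metabolite map and
keeps, per metabolite, the enzyme with the largest absolute correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core import FeatureMatrix

logger = logging.getLogger(__name__)

CATEGORIES = {
    (False, False): "RNA-Prot-",
    (True, False): "RNA+Prot-",
    (False, True): "RNA-Prot+",
    (True, True): "RNA+Prot+",
}


def pair_rna_protein(
    protein_ids,
    mapping: pd.DataFrame,
    rna_results: pd.DataFrame,
) -> pd.DataFrame:
    """Protein-centric pairing: keep the most rhythmic candidate transcript.

    ``mapping`` has columns (protein_id, transcript_id).  The transcript
    with the smallest adjusted p wins; ties go to the smallest raw p, then
    the lexicographically smallest transcript id.  Proteins without any
    candidate transcript are omitted and counted.
    """
    if mapping.empty:
        raise ValueError("empty protein-transcript mapping")
    cand = mapping[mapping["protein_id"].isin(protein_ids)].copy()
    cand = cand[cand["transcript_id"].isin(rna_results.index)]
    cand["adj_p"] = rna_results.loc[cand["transcript_id"], "adj_p"].to_numpy()
    cand["raw_p"] = rna_results.loc[cand["transcript_id"], "raw_p"].to_numpy()
    cand = cand.sort_values(
        ["protein_id", "adj_p", "raw_p", "transcript_id"], kind="stable"
    )
    pairs = cand.drop_duplicates("protein_id", keep="first")
    n_unpaired = len(set(protein_ids)) - pairs["protein_id"].nunique()
    logger.info("paired %d proteins to transcripts; %d proteins unpaired",
                len(pairs), n_unpaired)
    return pairs[["protein_id", "transcript_id"]].reset_index(drop=True)


def _window_profiles(
    matrix: FeatureMatrix, window_h: tuple[float, float] | None
) -> pd.DataFrame:
    means = matrix.timepoint_means()
    if window_h is not None:
        lo, hi = window_h
        cols = [c for c in means.columns if lo <= c <= hi]
        means = means[cols]
    return means


def pairwise_correlations(
    left: FeatureMatrix,
    right: FeatureMatrix,
    pairs: pd.DataFrame,
    left_results: pd.DataFrame | None = None,
    right_results: pd.DataFrame | None = None,
    window_h: tuple[float, float] | None = (30.0, 81.0),
) -> pd.DataFrame:
    """Pearson correlation of paired temporal profiles over a CT window.

    ``pairs`` has two columns: left and right feature ids (first and second
    column respectively).  Replicates are averaged per time point before
    correlating; only time points inside the closed window and present in
    both layers are used.  When rhythm results are supplied, each pair gets
    a rhythmicity category and, if both members are rhythmic, the circular
    phase difference (right - left) mod 24.
    """
    lcol, rcol = pairs.columns[:2]
    lmeans = _window_profiles(left, window_h)
    rmeans = _window_profiles(right, window_h)
    shared = [c for c in lmeans.columns if c in set(rmeans.columns)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared time points in the window")
    lm = lmeans[shared]
    rm = rmeans[shared]

    rows = []
    for lid, rid in zip(pairs[lcol], pairs[rcol]):
        x = lm.loc[lid].to_numpy(dtype=float)
        y = rm.loc[rid].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        row = {lcol: lid, rcol: rid, "pearson_r": r}
        if left_results is not None and right_results is not None:
            lr = bool(left_results.loc[lid, "rhythmic"])
            rr = bool(right_results.loc[rid, "rhythmic"])
            row["category"] = CATEGORIES[(lr, rr)]
            if lr and rr:
                row["phase_diff_h"] = float(
                    (right_results.loc[rid, "phase_h"]
                     - left_results.loc[lid, "phase_h"]) % 24.0
                )
            else:
                row["phase_diff_h"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    n_undef = int(out["pearson_r"].isna().sum())
    if n_undef:
        logger.info("%d pairs had undefined correlations (flagged NaN)", n_undef)
    return out


def compare_correlation_groups(
    group_a: np.ndarray, group_b: np.ndarray, exact_max_n: int = 50
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two value groups.

    Exact enumeration for small groups, normal approximation with tie
    correction otherwise.  Reports the effect direction (sign of the
    median difference).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    method = "exact" if max(len(a), len(b)) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "n_a": len(a),
        "n_b": len(b),
        "direction": float(np.sign(np.median(a) - np.median(b))),
    }


def phase_difference_distribution(
    pair_table: pd.DataFrame, bin_h: float = 3.0, period_h: float = 24.0
) -> pd.Series:
    """Histogram of circular phase differences over [0, period) bins.

    Only pairs with both members rhythmic (finite ``phase_diff_h``) enter;
    the modal bin(s) are logged.
    """
    d = pair_table["phase_diff_h"].to_numpy(dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no pairs with both members rhythmic")
    n_bins = int(round(period_h / bin_h))
    if not np.isclose(n_bins * bin_h, period_h):
        raise ValueError("bin width must divide the period")
    edges = bin_h * np.arange(n_bins + 1)
    counts, _ = np.histogram(d % period_h, bins=edges)
    out = pd.Series(counts, index=edges[:-1], name="count")
    modal = out.index[out == out.max()].tolist()
    logger.info("phase-difference modes at %s h", modal)
    return out


def cross_correlation(
    left_profile: np.ndarray,
    right_profile: np.ndarray,
    step_h: float = 3.0,
    max_lag_h: float = 12.0,
    min_overlap: int = 6,
) -> tuple[float, float]:
    """Best lag (hours) and correlation of two equally sampled profiles.

    The right profile is shifted by every lag in +-max_lag_h (multiples of
    the sampling step); Pearson r is computed on the truncated overlap.
    Positive lag means the right profile is delayed relative to the left.
    Ties in r go to the smallest \\|lag\\|.
    """
    x = np.asarray(left_profile, dtype=float)
    y = np.asarray(right_profile, dtype=float)
    max_shift = int(round(max_lag_h / step_h))
    best = None
    for shift in sorted(range(-max_shift, max_shift + 1), key=abs):
        if shift >= 0:
            # right delayed by shift: align x[t] with y[t + shift]
            xs = x[: len(x) - shift] if shift else x
            ys = y[shift:]
        else:
            xs, ys = x[-shift:], y[: len(y) + shift]
        ok = np.isfinite(xs) & np.isfinite(ys)
        if ok.sum() < min_overlap:
            continue
        if np.std(xs[ok]) == 0 or np.std(ys[ok]) == 0:
            continue
        r = float(np.corrcoef(xs[ok], ys[ok])[0, 1])
        if best is None or r > best[1] + 1e-12:
            best = (shift * step_h, r)
    if best is None:
        raise ValueError("insufficient overlap at every lag")
    return best


def pca_temporal(matrix: FeatureMatrix, n_components: int = 2) -> dict:
    """Project time points onto the first principal axes of the layer.

    Features are centred; the observations are replicate-averaged time
    points, so the scores trace the system's trajectory through state
    space over circadian time.
    """
    means = matrix.timepoint_means()
    if means.shape[1] < 3:
        raise ValueError("PCA needs >= 3 time points")
    x = means.to_numpy(dtype=float).T  # time points x features
    x = x - x.mean(axis=0, keepdims=True)
    pca = PCA(n_components=min(n_components, min(x.shape) - 0))
    scores = pca.fit_transform(x)
    return {
        "scores": pd.DataFrame(
            scores[:, :n_components],
            index=means.columns,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])][:n_components],
        ),
        "variance_fraction": pca.explained_variance_ratio_[:n_components],
    }


# ---------------------------------------------------------------------------
# Enzyme-metabolite integration


def map_enzyme_metabolites(
    enzyme_map: pd.DataFrame, protein_ids, metabolite_ids
) -> pd.DataFrame:
    """All (protein, metabolite) candidate pairs present in both datasets.

    Rows of the map referencing entities absent from either dataset are
    dropped and counted; duplicate rows collapse to one pair.
    """
    if enzyme_map.empty:
        raise ValueError("empty enzyme-metabolite map")
    m = enzyme_map[["protein_id", "metabolite_id"]].drop_duplicates()
    n_before = len(m)
    m = m[m["protein_id"].isin(set(protein_ids))
          & m["metabolite_id"].isin(set(metabolite_ids))]
    logger.info("enzyme map: %d/%d pairs present in both datasets",
                len(m), n_before)
    return m.reset_index(drop=True)


def best_match_pairs(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Keep, per metabolite, the enzyme pair with the largest \\|r\\|.

    Ties on \\|r\\| prefer the positive correlation, then the
    lexicographically smallest protein id; metabolites whose candidate
    correlations are all undefined are dropped with a warning.
    """
    t = pair_table.dropna(subset=["pearson_r"]).copy()
    n_dropped = pair_table["metabolite_id"].nunique() - t["metabolite_id"].nunique()
    if n_dropped:
        logger.warning("%d metabolites had no defined correlation", n_dropped)
    t["abs_r"] = t["pearson_r"].abs()
    t = t.sort_values(
        ["metabolite_id", "abs_r", "pearson_r", "protein_id"],
        ascending=[True, False, False, True],
        kind="stable",
    )
    return (t.drop_duplicates("metabolite_id", keep="first")
            .drop(columns="abs_r")
            .reset_index(drop=True))
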