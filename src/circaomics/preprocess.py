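"""Layer-specific preprocessing: expression filtering, detrending and
normalization.

Transcripts (FPKM scale) are filtered by a two-component Gaussian-mixture
threshold on log10 mean expression: the cutoff is a quantile (0.95 by
default) of the lowly-expressed component, mapped back to the linear scale.
Protein TMT reporter channels are normalized by linear regression in log
space and the two multiplexed sets assembled into one time course via
pooled-reference log-ratios (or per-set mean-centring).  Metabolite
features pass a pooled-QC coefficient-of-variation filter and a
retention-time exclusion window, and samples are normalized by the
log-ratio (median-of-log-ratios) method.  All temporal profiles can be
linearly detrended before rhythm detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .core import FeatureMatrix, TimeGrid

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Expression threshold (Gaussian mixture on log10 abundance)


@dataclass
class MixtureThreshold:
    """Two-component GMM fit of log10 expression and the derived cutoff."""

    means_log10: tuple[float, float]  # (low, high)
    sds_log10: tuple[float, float]
    weights: tuple[float, float]
    threshold_linear: float
    percentile_used: float
    n_features_fit: int
    converged: bool
    n_iter: int


def fit_expression_threshold(
    mean_expression: np.ndarray,
    percentile: float = 0.95,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MixtureThreshold:
    """Fit a 2-component Gaussian mixture to log10 expression and derive
    the expressed/lowly-expressed cutoff.

    The threshold is the fitted ``percentile`` quantile of the component
    with the smaller mean, returned on the linear scale.  Zeros are
    excluded (log undefined); EM is initialized deterministically by a
    median split of the log values.
    """
    x = np.asarray(mean_expression, dtype=float)
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative")
    pos = x[x > 0]
    if pos.size < 50:
        raise ValueError(f"need >= 50 positive values, got {pos.size}")
    logx = np.log10(pos).reshape(-1, 1)

    med = np.median(logx)
    lo, hi = logx[logx[:, 0] <= med], logx[logx[:, 0] > med]
    means_init = np.array([[lo.mean()], [hi.mean()]])
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=means_init,
        weights_init=np.array([0.5, 0.5]),
        precisions_init=np.array([[[1.0 / max(lo.var(), 1e-6)]],
                                  [[1.0 / max(hi.var(), 1e-6)]]]),
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(logx)
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(lower bound {gm.lower_bound_:.4g})"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    low = int(np.argmin(means))
    order = [low, 1 - low]
    thr_log10 = stats.norm.ppf(percentile, loc=means[low], scale=sds[low])
    return MixtureThreshold(
        means_log10=(float(means[order[0]]), float(means[order[1]])),
        sds_log10=(float(sds[order[0]]), float(sds[order[1]])),
        weights=(float(weights[order[0]]), float(weights[order[1]])),
        threshold_linear=float(10 ** thr_log10),
        percentile_used=percentile,
        n_features_fit=int(pos.size),
        converged=True,
        n_iter=int(gm.n_iter_),
    )


def apply_expression_filter(
    matrix: FeatureMatrix, threshold: MixtureThreshold | float
) -> FeatureMatrix:
    """Retain features whose mean across all samples is >= the threshold."""
    thr = (threshold.threshold_linear
           if isinstance(threshold, MixtureThreshold) else float(threshold))
    means = np.nanmean(matrix.values(), axis=1)
    keep = means >= thr
    n_kept = int(keep.sum())
    logger.info("expression filter: kept %d/%d features at >= %.4g",
                n_kept, matrix.n_features, thr)
    if n_kept == 0:
        logger.warning("expression filter removed every feature")
    return FeatureMatrix(matrix.data.loc[keep], matrix.grid,
                         matrix.layer, matrix.scale)


# ---------------------------------------------------------------------------
# Linear detrending


def linear_detrend_profile(values: np.ndarray, times_h: np.ndarray) -> np.ndarray:
    """Fit and subtract an OLS straight line in time from one profile.

    Missing values are preserved; replicates are regressed against their
    time point's hour.  Requires >= 3 non-missing values.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times_h, dtype=float)
    finite = np.isfinite(y)
    if finite.sum() < 3:
        raise ValueError("detrending needs >= 3 non-missing values")
    coef = np.polyfit(t[finite], y[finite], 1)
    out = y - np.polyval(coef, t)
    out[~finite] = np.nan
    return out


def linear_detrend(matrix: FeatureMatrix) -> FeatureMatrix:
    """Detrend every feature profile against CT hours (vectorized OLS)."""
    x = matrix.values()
    t = matrix.grid.time_array()
    if np.all(np.isfinite(x)):
        design = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
        resid = x - (design @ beta).T
    else:
        resid = np.vstack([
            linear_detrend_profile(x[i], t) for i in range(x.shape[0])
        ])
    data = pd.DataFrame(resid, index=matrix.data.index,
                        columns=matrix.data.columns)
    # residuals of a positive-scale fit are not positive-scale any more
    return FeatureMatrix(data, matrix.grid, matrix.layer, "log"
                         if matrix.scale == "log" else "linear")


# ---------------------------------------------------------------------------
# TMT proteomics


@dataclass(frozen=True)
class TMTSetLayout:
    """Channel -> sample assignment of one multiplexed TMT set."""

    set_id: str
    channels: tuple[str, ...]  # column names, in channel order
    reference_channel: str | None = None  # pooled-sample channel, if any

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique within a set")
        if (self.reference_channel is not None
                and self.reference_channel not in self.channels):
            raise ValueError("reference channel not among the set's channels")

    @property
    def sample_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c != self.reference_channel)


def normalize_tmt_channels(
    set_matrix: pd.DataFrame, layout: TMTSetLayout
) -> pd.DataFrame:
    """Remove global per-channel abundance distortions by log-space OLS.

    Each channel's log intensities are regressed on the leave-one-out mean
    of the other channels' log intensities (per protein); the fitted affine
    distortion is inverted, aligning every channel to slope 1 / intercept 0
    against the consensus.  Requires >= 3 proteins with finite values per
    channel.
    """
    cols = list(layout.channels)
    mat = set_matrix[cols].to_numpy(dtype=float)
    if np.any(mat[np.isfinite(mat)] <= 0):
        raise ValueError("TMT intensities must be positive")
    logm = np.log(mat)
    out = logm.copy()
    n_ch = len(cols)
    for j in range(n_ch):
        others = [k for k in range(n_ch) if k != j]
        consensus = np.nanmean(logm[:, others], axis=1)
        y = logm[:, j]
        finite = np.isfinite(y) & np.isfinite(consensus)
        if finite.sum() < 3:
            raise ValueError(
                f"channel {cols[j]!r} has {int(finite.sum())} usable values; "
                "need >= 3"
            )
        slope, intercept = np.polyfit(consensus[finite], y[finite], 1)
        out[:, j] = (y - intercept) / slope
    return pd.DataFrame(np.exp(out), index=set_matrix.index, columns=cols)


def assemble_tmt_timecourse(
    set1: pd.DataFrame,
    set2: pd.DataFrame,
    layout1: TMTSetLayout,
    layout2: TMTSetLayout,
    mode: str = "reference",
) -> FeatureMatrix:
    """Join two TMT sets into one log-scale time course.

    ``reference`` mode takes log(channel / pooled-reference channel) within
    each set; ``mean_centre`` subtracts each protein's within-set mean log
    intensity.  Only proteins quantified in both sets are kept; sample
    channels must be named ``CT{h}_r{rep}`` so the grid concatenates on the
    time axis.
    """
    if mode not in ("reference", "mean_centre"):
        raise ValueError(f"unknown assembly mode {mode!r}")
    shared = set1.index.intersection(set2.index)
    n_dropped = len(set1.index.union(set2.index)) - len(shared)
    if n_dropped:
        logger.info("TMT assembly: dropped %d proteins absent from one set",
                    n_dropped)
    parts = []
    for m, layout in ((set1, layout1), (set2, layout2)):
        sub = m.loc[shared]
        samples = list(layout.sample_channels)
        logs = np.log(sub[samples].to_numpy(dtype=float))
        if mode == "reference":
            if layout.reference_channel is None:
                raise ValueError(
                    f"set {layout.set_id!r} has no reference channel"
                )
            ref = np.log(sub[layout.reference_channel].to_numpy(dtype=float))
            vals = logs - ref[:, None]
        else:
            all_logs = np.log(sub[list(layout.channels)].to_numpy(dtype=float))
            vals = logs - np.nanmean(all_logs, axis=1, keepdims=True)
        parts.append(pd.DataFrame(vals, index=shared, columns=samples))
    joined = pd.concat(parts, axis=1)
    grid = TimeGrid.from_columns(joined.columns)
    order = np.argsort(np.asarray(grid.times), kind="stable")
    joined = joined.iloc[:, order]
    return FeatureMatrix(joined, TimeGrid.from_columns(joined.columns),
                         "protein", "log")


# ---------------------------------------------------------------------------
# Metabolomics


def qc_cv_filter(
    matrix: FeatureMatrix,
    qc_data: pd.DataFrame,
    cv_max: float = 0.30,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Keep features whose pooled-QC coefficient of variation is < cv_max.

    CV = sd/mean on the linear scale over the QC injections (the standard
    metabolomics stability criterion); the report lists every feature's CV
    and whether it passed.
    """
    if qc_data.shape[1] < 2:
        raise ValueError("need >= 2 QC samples to compute a CV")
    qc = qc_data.loc[matrix.feature_ids].to_numpy(dtype=float)
    cv = np.nanstd(qc, axis=1, ddof=1) / np.nanmean(qc, axis=1)
    keep = cv < cv_max
    report = pd.DataFrame(
        {"cv": cv, "passed": keep}, index=matrix.feature_ids
    )
    logger.info("QC CV filter: kept %d/%d features at CV < %g",
                int(keep.sum()), matrix.n_features, cv_max)
    return matrix.subset_features(matrix.feature_ids[keep]), report


def rt_window_filter(
    matrix: FeatureMatrix,
    retention_times_min: pd.Series,
    window_min: tuple[float, float] = (19.15, 19.35),
) -> FeatureMatrix:
    """Exclude features eluting inside a closed retention-time window.

    Used to drop an artefact-prone chromatographic region; the window is
    closed on both ends.
    """
    lo, hi = window_min
    if lo > hi:
        raise ValueError("invalid retention-time window (min > max)")
    missing = matrix.feature_ids.difference(retention_times_min.index)
    if len(missing):
        raise ValueError(f"missing retention times for {len(missing)} features")
    rt = retention_times_min.loc[matrix.feature_ids].to_numpy(dtype=float)
    keep = ~((rt >= lo) & (rt <= hi))
    logger.info("RT filter [%g, %g] min: excluded %d/%d features",
                lo, hi, int((~keep).sum()), matrix.n_features)
    return matrix.subset_features(matrix.feature_ids[keep])


def sample_normalize_logratio(
    matrix: FeatureMatrix,
) -> tuple[FeatureMatrix, pd.Series]:
    """Median-of-log-ratios normalization across samples.

    The reference profile is the per-feature median across samples; each
    sample's factor is the median over features of log(sample/reference),
    and the sample is divided by exp(factor).  Returns the normalized
    matrix and the per-sample factors for reuse.
    """
    x = matrix.values()
    if np.any(x[np.isfinite(x)] <= 0):
        raise ValueError("log-ratio normalization needs positive intensities")
    if np.any(np.all(~np.isfinite(x), axis=0)):
        raise ValueError("a sample has all-missing values")
    ref = np.nanmedian(x, axis=1)
    logratio = np.log(x) - np.log(ref)[:, None]
    factors = np.nanmedian(logratio, axis=0)
    normed = x / np.exp(factors)[None, :]
    data = pd.DataFrame(normed, index=matrix.data.index,
                        columns=matrix.data.columns)
    return (FeatureMatrix(data, matrix.grid, matrix.layer, matrix.scale),
            pd.Series(factors, index=matrix.data.columns, name="log_factor"))


# ---------------------------------------------------------------------------
# qPCR


def delta_ct_quantify(ct_target: float, ct_reference: float) -> float:
    """Relative qPCR quantification by the 2^-dCt method."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))
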