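"""Synthetic coupled multi-omics time courses with known rhythmic structure.

The generator emulates the statistical features of a constant-condition
circadian time course in cultured cells: a bimodal log-abundance
distribution (lowly expressed vs expressed features), a rhythmic
subpopulation carrying a low-amplitude 24-h cosine (amplitude ratios of
two-fold or less) with peak phases concentrated at CT0 and CT12,
per-feature linear drift, replicate structure, a protein layer that tracks
its transcript with a 0-h or ~12-h delay, and a metabolite layer coupled
(positively or negatively) to enzyme profiles through a
protein -> EC number -> metabolite map, with pooled-QC injections for the
coefficient-of-variation filter.

Rhythms are generated multiplicatively: the cosine is added to the natural
log of abundance, so the max/min amplitude ratio of the noiseless curve is
scale-invariant and equals exp(2a) for log-amplitude a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureMatrix, TimeGrid, circular_difference_h

_LN10 = np.log(10.0)

TRUTH_COLUMNS = [
    "feature_id", "layer", "rhythmic", "true_period_h", "true_phase_h",
    "true_amplitude_ratio", "partner_id", "delay_h", "coupling_sign",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic generator.

    Baseline log10-abundance is a two-component mixture (lowly expressed
    and expressed); rhythm amplitude is expressed as the max/min fold ratio
    of the noiseless curve; drift and noise act in natural-log space.
    """

    n_features: int = 1000
    fraction_rhythmic: float = 0.1
    period_h: float = 24.0
    phase_modes_h: tuple[float, ...] = (0.0, 12.0)
    phase_concentration_h: float = 1.5  # sd of each wrapped-normal mode
    amplitude_ratio_range: tuple[float, float] = (1.2, 2.0)
    baseline_low_mean_log10: float = -1.0
    baseline_low_sd_log10: float = 0.5
    baseline_high_mean_log10: float = 1.5
    baseline_high_sd_log10: float = 0.7
    baseline_expressed_weight: float = 0.6
    drift_slope_sd: float = 0.002  # ln-units per hour
    noise_sd: float = 0.1  # ln-units
    start_h: float = 24.0
    end_h: float = 81.0
    step_h: float = 3.0
    n_replicates: int = 1
    protein_delay_choices_h: tuple[float, ...] = (0.0, 12.0)
    protein_coupling_strength: float = 1.0  # attenuation of the shared rhythm
    coupling_sign_prob: float = 0.5  # P(positive enzyme-metabolite coupling)
    n_qc_injections: int = 5
    qc_noise_sd: float = 0.1  # ln-units of technical noise in QC injections
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if not 0.0 <= self.fraction_rhythmic <= 1.0:
            raise ValueError("fraction_rhythmic must be in [0, 1]")
        if self.amplitude_ratio_range[0] < 1.0:
            raise ValueError("amplitude ratios are max/min folds, >= 1")
        if any(not 0 <= m < self.period_h for m in self.phase_modes_h):
            raise ValueError("phase modes must lie in [0, period)")

    def grid(self) -> TimeGrid:
        return TimeGrid.regular(self.start_h, self.end_h, self.step_h,
                                self.n_replicates)


def _empty_truth(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {c: [None] * n for c in TRUTH_COLUMNS}
    )


def _sample_phases(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Equal-weight wrapped-normal mixture at the configured peak modes."""
    modes = np.asarray(cfg.phase_modes_h, dtype=float)
    which = rng.integers(0, len(modes), size=n)
    raw = modes[which] + rng.normal(0.0, cfg.phase_concentration_h, size=n)
    return raw % cfg.period_h


def _noiseless_log_profiles(
    log_base: np.ndarray,
    rhythmic: np.ndarray,
    phases: np.ndarray,
    amp_ratio: np.ndarray,
    slopes: np.ndarray,
    times: np.ndarray,
    period_h: float,
) -> np.ndarray:
    """Per-feature natural-log profiles before noise (features x samples)."""
    t = times[None, :]
    drift = slopes[:, None] * (t - t[0, 0])
    log_amp = np.where(rhythmic, np.log(amp_ratio) / 2.0, 0.0)
    cosine = log_amp[:, None] * np.cos(
        2 * np.pi * (t - phases[:, None]) / period_h
    )
    return log_base[:, None] + drift + np.where(rhythmic[:, None], cosine, 0.0)


def simulate_layer(
    config: SimulationConfig, layer: str = "transcript"
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Simulate one layer of independent features with planted rhythms.

    Returns a linear-scale feature matrix (FPKM-like abundances) and the
    ground-truth table.  Identical seed gives identical output.
    """
    grid = config.grid()
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    prefix = {"transcript": "TX", "protein": "PR", "metabolite": "MB"}.get(
        layer, layer[:2].upper()
    )
    ids = [f"{prefix}{i:05d}" for i in range(n)]

    expressed = rng.random(n) < config.baseline_expressed_weight
    log10_base = np.where(
        expressed,
        rng.normal(config.baseline_high_mean_log10,
                   config.baseline_high_sd_log10, n),
        rng.normal(config.baseline_low_mean_log10,
                   config.baseline_low_sd_log10, n),
    )
    rhythmic = rng.random(n) < config.fraction_rhythmic
    phases = _sample_phases(rng, n, config)
    amp = rng.uniform(*config.amplitude_ratio_range, size=n)
    slopes = rng.normal(0.0, config.drift_slope_sd, size=n)

    times = grid.time_array()
    log_prof = _noiseless_log_profiles(
        log10_base * _LN10, rhythmic, phases, amp, slopes, times,
        config.period_h,
    )
    noise = rng.normal(0.0, config.noise_sd, size=log_prof.shape)
    data = pd.DataFrame(
        np.exp(log_prof + noise), index=pd.Index(ids, name="feature_id"),
        columns=grid.column_names(),
    )
    truth = pd.DataFrame({
        "feature_id": ids,
        "layer": layer,
        "rhythmic": rhythmic,
        "true_period_h": np.where(rhythmic, config.period_h, np.nan),
        "true_phase_h": np.where(rhythmic, phases, np.nan),
        "true_amplitude_ratio": np.where(rhythmic, amp, np.nan),
        "partner_id": None,
        "delay_h": np.nan,
        "coupling_sign": np.nan,
    })
    return FeatureMatrix(data, grid, layer, "linear"), truth


def simulate_coupled_protein_layer(
    rna: FeatureMatrix, rna_truth: pd.DataFrame, config: SimulationConfig
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Simulate a protein layer tracking transcript rhythms with delays.

    Each protein has its own baseline but inherits its partner transcript's
    noiseless rhythmic component shifted by a delay drawn from
    ``protein_delay_choices_h`` and attenuated by
    ``protein_coupling_strength``; noise is independent of the transcript
    layer.  Non-rhythmic transcripts give non-rhythmic proteins.
    """
    if len(rna_truth) != rna.n_features:
        raise ValueError("truth table does not match the transcript matrix")
    grid = rna.grid
    rng = np.random.default_rng(config.seed + 1)
    n = rna.n_features
    ids = [f"PR{i:05d}" for i in range(n)]
    partner = list(rna_truth["feature_id"])

    rhythmic = rna_truth["rhythmic"].to_numpy(dtype=bool)
    delays = rng.choice(np.asarray(config.protein_delay_choices_h), size=n)
    phases = (rna_truth["true_phase_h"].to_numpy(dtype=float) + delays) % config.period_h
    amp_rna = rna_truth["true_amplitude_ratio"].to_numpy(dtype=float)
    # attenuation scales the log-amplitude, hence the ratio's exponent
    amp = np.exp(np.log(np.where(rhythmic, amp_rna, 1.0))
                 * config.protein_coupling_strength)

    log10_base = rng.normal(config.baseline_high_mean_log10,
                            config.baseline_high_sd_log10, n)
    slopes = rng.normal(0.0, config.drift_slope_sd, size=n)
    log_prof = _noiseless_log_profiles(
        log10_base * _LN10, rhythmic, np.nan_to_num(phases), amp, slopes,
        grid.time_array(), config.period_h,
    )
    noise = rng.normal(0.0, config.noise_sd, size=log_prof.shape)
    data = pd.DataFrame(
        np.exp(log_prof + noise), index=pd.Index(ids, name="feature_id"),
        columns=grid.column_names(),
    )
    truth = pd.DataFrame({
        "feature_id": ids,
        "layer": "protein",
        "rhythmic": rhythmic,
        "true_period_h": np.where(rhythmic, config.period_h, np.nan),
        "true_phase_h": np.where(rhythmic, phases, np.nan),
        "true_amplitude_ratio": np.where(rhythmic, amp, np.nan),
        "partner_id": partner,
        "delay_h": delays,
        "coupling_sign": 1.0,
    })
    return FeatureMatrix(data, grid, "protein", "linear"), truth


def make_enzyme_map(
    protein_ids, n_metabolites: int, n_decoys: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Random protein -> EC -> metabolite map with one designated partner.

    Each metabolite is linked to one designated enzyme plus ``n_decoys``
    other enzymes, mimicking the many-to-many EC/KEGG annotation; the
    designated partner is the first row for each metabolite.
    """
    rng = np.random.default_rng(seed)
    protein_ids = list(protein_ids)
    rows = []
    for i in range(n_metabolites):
        mid = f"MB{i:05d}"
        chosen = rng.choice(len(protein_ids), size=min(n_decoys + 1, len(protein_ids)),
                            replace=False)
        for j, c in enumerate(chosen):
            rows.append({
                "protein_id": protein_ids[c],
                "ec_number": f"EC:{c % 7 + 1}.{c % 13 + 1}.{c % 3 + 1}.{c}",
                "metabolite_id": mid,
                "designated": j == 0,
            })
    return pd.DataFrame(rows)


def simulate_coupled_metabolite_layer(
    protein: FeatureMatrix,
    protein_truth: pd.DataFrame,
    enzyme_map: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Simulate metabolites coupled to designated enzyme profiles.

    Each metabolite's noiseless log profile is sign x (the centred noiseless
    log profile of its designated enzyme) on top of its own baseline, with
    sign positive with probability ``coupling_sign_prob`` (substrates and
    products can track an enzyme in either direction).  Pooled-QC
    injections (columns ``QC_i``) are repeated measurements of the
    per-feature grand mean with technical noise, supporting the CV filter.
    """
    grid = protein.grid
    rng = np.random.default_rng(config.seed + 2)
    truth_idx = protein_truth.set_index("feature_id")

    metabolite_ids = list(dict.fromkeys(enzyme_map["metabolite_id"]))
    if "designated" in enzyme_map.columns:
        partners = (enzyme_map[enzyme_map["designated"]]
                    .set_index("metabolite_id")["protein_id"])
    else:
        partners = enzyme_map.groupby("metabolite_id")["protein_id"].first()
    missing = [m for m in metabolite_ids if m not in partners.index]
    if missing:
        raise ValueError(f"metabolite(s) without mapped protein: {missing[:5]}")

    times = grid.time_array()
    n = len(metabolite_ids)
    signs = np.where(rng.random(n) < config.coupling_sign_prob, 1.0, -1.0)
    log10_base = rng.normal(config.baseline_high_mean_log10,
                            config.baseline_high_sd_log10, n)
    rows, truth_rows = [], []
    for i, mid in enumerate(metabolite_ids):
        pid = partners[mid]
        if pid not in truth_idx.index:
            raise ValueError(f"mapped protein {pid} absent from the protein layer")
        prow = truth_idx.loc[pid]
        rhythmic = bool(prow["rhythmic"])
        base = log10_base[i] * _LN10
        if rhythmic:
            amp = float(prow["true_amplitude_ratio"])
            phase = float(prow["true_phase_h"])
            log_amp = np.log(amp) / 2.0
            rhythm = log_amp * np.cos(2 * np.pi * (times - phase) / config.period_h)
            prof = base + signs[i] * rhythm
            phase_m = phase if signs[i] > 0 else (phase + config.period_h / 2) % config.period_h
        else:
            prof = np.full_like(times, base)
            phase_m, amp = np.nan, np.nan
        rows.append(prof)
        truth_rows.append({
            "feature_id": mid,
            "layer": "metabolite",
            "rhythmic": rhythmic,
            "true_period_h": config.period_h if rhythmic else np.nan,
            "true_phase_h": phase_m,
            "true_amplitude_ratio": amp,
            "partner_id": pid,
            "delay_h": 0.0,
            "coupling_sign": signs[i],
        })
    log_prof = np.asarray(rows)
    noise = rng.normal(0.0, config.noise_sd, size=log_prof.shape)
    data = pd.DataFrame(
        np.exp(log_prof + noise),
        index=pd.Index(metabolite_ids, name="feature_id"),
        columns=grid.column_names(),
    )
    # pooled-QC injections: repeated draws around the per-feature grand mean
    grand = log_prof.mean(axis=1)
    for q in range(config.n_qc_injections):
        data[f"QC_{q + 1}"] = np.exp(
            grand + rng.normal(0.0, config.qc_noise_sd, size=n)
        )
    qc_cols = [f"QC_{q + 1}" for q in range(config.n_qc_injections)]
    sample_data = data.drop(columns=qc_cols)
    matrix = FeatureMatrix(sample_data, grid, "metabolite", "linear")
    matrix.qc_data = data[qc_cols]  # type: ignore[attr-defined]
    return matrix, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Detection evaluation against ground truth


@dataclass
class DetectionReport:
    """Confusion summary of a rhythm scan against simulation truth."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    realized_fdr: float
    phase_errors_h: np.ndarray  # circular errors among true positives

    @property
    def median_abs_phase_error_h(self) -> float:
        if self.phase_errors_h.size == 0:
            return np.nan
        return float(np.median(np.abs(self.phase_errors_h)))


def evaluate_detection(results: pd.DataFrame, truth: pd.DataFrame) -> DetectionReport:
    """Score detected rhythms against the generating truth.

    Realized FDR = FP/(FP+TP), defined as 0 when nothing is flagged; phase
    errors are circular differences (estimated - true peak CT) among true
    positives.
    """
    t = truth.set_index("feature_id")
    if set(results.index) != set(t.index):
        raise ValueError("results and truth cover different feature sets")
    t = t.loc[results.index]
    called = results["rhythmic"].to_numpy(dtype=bool)
    real = t["rhythmic"].to_numpy(dtype=bool)
    tp = int(np.sum(called & real))
    fp = int(np.sum(called & ~real))
    tn = int(np.sum(~called & ~real))
    fn = int(np.sum(~called & real))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    fdr = fp / (fp + tp) if (fp + tp) else 0.0
    tp_mask = called & real
    errs = circular_difference_h(
        results.loc[tp_mask, "phase_h"].to_numpy(dtype=float),
        t.loc[tp_mask, "true_phase_h"].to_numpy(dtype=float),
    )
    return DetectionReport(tp, fp, tn, fn, sens, fdr, errs)
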