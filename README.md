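# circaomics

Rhythm discovery and multi-omics integration for circadian time-course
studies in constant conditions — built for experiments like a 3-h-resolution
sampling of cultured *Drosophila* S2 cells over CT24–CT81, where 24-h
oscillations in transcripts, proteins and metabolites must be detected
without any canonical clock gene as a positive control.

The package covers the full analysis path:

- **Preprocessing** — expressed-transcript filtering by a two-component
  Gaussian-mixture threshold on log10 FPKM, per-profile linear detrending,
  TMT reporter-channel normalization by log-space regression with two-set
  assembly via a pooled reference channel, metabolomics pooled-QC CV
  filtering, retention-time exclusion and median-of-log-ratios sample
  normalization, and 2^−ΔCt qPCR quantification.
- **Rhythm detection** — a rank-concordance (JTK-style) scan against a
  lattice of cosine reference waveforms (periods 21–27 h, all lags on the
  sampling grid), with an *exact* permutation null per waveform, Bonferroni
  adjustment over the scanned waveforms, max/min amplitude ratios, and a
  genome-wide permutation FDR that removes detected positives before
  permuting time labels.
- **Integration** — protein-centric RNA–protein pairing (most rhythmic
  transcript per protein), Pearson correlation of temporal profiles over a
  shared CT window, rhythmicity categories with Wilcoxon rank-sum
  comparisons, circular phase-lag distributions, truncated temporal
  cross-correlation, PCA state trajectories, and enzyme–metabolite
  best-match pairing through a protein → EC → metabolite map.
- **Set statistics** — Fisher-exact overlap of rhythmic sets (across
  methods, temperatures or thresholds), hypergeometric over-representation
  with BH correction, phase histograms.
- **Synthetic data** — a generator of coupled transcript/protein/metabolite
  layers with known ground truth (bimodal log-abundance, low-amplitude
  24-h cosines with peak phases at CT0/CT12, linear drift, 0/12-h protein
  delays, signed enzyme–metabolite coupling, pooled-QC injections), so the
  whole pipeline is testable end to end.

## The statistic

For a profile x sampled at times with reference waveform
c(t) = cos(2π(t − lag)/period), the test statistic is

    S = Σ_{(i,j): c_i < c_j} sgn(x_j − x_i)

summing over sample pairs ordered by the reference value; pairs tied in the
reference (including replicates at one time point) are skipped and data
ties contribute 0. Under random orderings the exact null of S follows from
a convolution of Gaussian binomials over the waveform's tie-group sizes
(S = M − 2k, with M the number of counted pairs and k the number of
discordant ones). The per-feature one-sided p-value of the best waveform is
Bonferroni-corrected by the number of distinct waveforms K
(adj_p = min(1, K·p)), and the study-wide FDR is estimated as

    FDR ≈ mean permuted positive count (after positive removal, rescaled)
          ─────────────────────────────────────────────────────────────
                     observed positive count

with an add-one empirical p-value from the permutation distribution.

## Worked example

```python
from circaomics.simulate import SimulationConfig, simulate_layer, evaluate_detection
from circaomics.preprocess import linear_detrend
from circaomics.rhythm import RhythmParams, detect_rhythms, permutation_fdr

cfg = SimulationConfig(n_features=1000, fraction_rhythmic=0.1,
                       noise_sd=0.1, seed=1)
matrix, truth = simulate_layer(cfg)            # FPKM-like, CT24-CT81 @ 3 h
detrended = linear_detrend(matrix)
results = detect_rhythms(detrended, RhythmParams(), amplitude_source=matrix)
report = evaluate_detection(results, truth)
fdr = permutation_fdr(detrended, RhythmParams(), n_permutations=200,
                      seed=2, results=results)
print(f"rhythmic calls: {int(results['rhythmic'].sum())}")
print(f"sensitivity {report.sensitivity:.2f}, "
      f"realized FDR {report.realized_fdr:.2f}, "
      f"estimated FDR {fdr.fdr_estimate:.2f}")
```

prints

```
rhythmic calls: 124
sensitivity 0.99, realized FDR 0.20, estimated FDR 0.25
```

i.e. 124 of 1,000 features are called rhythmic at adjusted p < 0.05; 99% of
the 100 planted rhythms are found, about a fifth of the calls are false,
and the permutation estimator — which never sees the ground truth — lands
within a few points of that realized rate.

The same analysis runs from the shell:

```
circaomics simulate --n-features 1000 --seed 1 --out m.tsv
circaomics detrend m.tsv --out d.tsv
circaomics detect d.tsv --period-min 21 --period-max 27 --adj-p 0.05 --out r.tsv
circaomics fdr d.tsv -B 200 --seed 2 --out-dir fdr/
circaomics run --seed 1 --out-dir study/     # full coupled 3-layer study
```

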