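# Methods

This note records what `srcflow` computes, which knobs exist, why their
defaults are what they are, and where the implementation makes choices a
user should know about before trusting a result.

## 1. Scope and model of the data

`srcflow` analyzes **source-resolved EEG** from a two-group (HC vs. CTD)
flanker-task study design: per subject, a set of independent components
(ICs) with equivalent-dipole locations and trial-locked activation time
series spanning −2000…+2000 ms around stimulus onset. Two sampling rates
are used deliberately: 250 Hz for spectral-power analysis (wavelets need
the bandwidth) and 100 Hz for connectivity (MVAR models want short lag
horizons and well-conditioned covariances).

The package ships a full synthetic-data generator (`srcflow.synthio`)
so that every analysis stage can be exercised against planted ground
truth. The generator is *not* a biophysical simulator: there is no
forward/inverse model, no volume conduction, and the "scalp map" feature
used in IC clustering is an explicit inverse-square geometry proxy. Its
purpose is statistical: produce cohorts whose behavioral tables, dipole
geometry, spectral bursts and directed-coupling effects are known
exactly, so recovery can be measured.

### Cohort and task defaults

Defaults mirror the intended study design: 35 HC and 60 CTD subjects,
ages 8–12; 72 congruent and 144 incongruent trials per subject; lognormal
reaction times with a 1300 ms response deadline and a 2% lapse rate
(no-response trials count as errors and are excluded from RT statistics);
CTD carries a −57 ms latent mean-RT shift, a male-enriched gender ratio
(80% vs. 46%), and populated tic-severity instruments.

### Signal generator

Sources follow a stationary MVAR(p) network with unit-variance
innovations, validated for stability via the companion-matrix spectral
radius and burned in for 500 samples so epochs contain no start-up
transient. Group effects are planted two ways:

* **Coupling effects** multiply one directed coefficient a_ij(r) for CTD
  subjects inside a post-stimulus window (default: edge 0→1, ×2.0,
  100–700 ms). `stable_random_network(ensure_edges=…)` forces the planted
  edge's lag-1 coefficient to be nonzero — a multiplicative effect on a
  zero coefficient would silently vanish.
* **Power effects** add a band-limited sinusoidal burst with Tukey ramps
  (25 ms), amplitude-calibrated from the pre-stimulus band power so that a
  `db_offset` of x dB targets an x dB in-band power increase. The
  calibration is approximate: band-edge and leakage losses mean a 2 dB
  target measures ≈1.7 dB through a band-pass filter and less through the
  wavelet ERSP (time–frequency smoothing). Tests therefore assert
  detectability and group ordering, not exact dB recovery.

## 2. ERSP

Per IC, single-trial power comes from Morlet wavelets
(`mne.time_frequency.tfr_array_morlet`) on the full epoch at 250 Hz,
with frequencies 2–50 Hz in 1 Hz steps and EEGLAB-style cycles
`(3, 0.5)`: 3 cycles at the lowest frequency growing linearly to
3·0.5·(f_max/f_min) at the highest. Power is averaged over trials
*before* baseline conversion; the map is then sampled at the centers of
1-s windows advanced in 25 ms steps.

Window positions are counted in **milliseconds**, not samples:
`n_positions = (epoch_ms − window_ms) / step_ms` with the final endpoint
dropped, giving 120 positions for a 4-s epoch. (25 ms is 6.25 samples at
250 Hz; sample-domain stepping would silently change the grid.)

Baseline normalization is dB relative to the per-frequency mean power in
−550…−50 ms: `10·log10(P/P_baseline)`. Doubled power is exactly
+3.0103 dB; white noise gives ≈0 dB everywhere (mean bias < 0.1 dB at
500 trials — verified in the acceptance suite). Band × window features
use theta 4–7, alpha 8–12, low beta 13–20, high beta 20–30 Hz (inclusive
edges; 20 Hz intentionally belongs to both beta bands) crossed with
early (0–200 ms) and late (250–600 ms) windows.

## 3. IC clustering

Study-level k-means (k = 12, 50 restarts, best inertia wins) on a joint
feature space of four blocks: dipole location (3 dims), ERP (trial
average 0–600 ms resampled to 32 points, PCA → 4 dims), ERSP (8 band ×
window dB means, PCA → 4 dims), and scalp map (inverse-square geometry
proxy over 20 fixed virtual sensors, PCA → 6 dims). Each block is
centered and scaled to unit total variance, then the dipole block is
weighted ×10 so it carries 100× the variance of each other block —
clusters are primarily anatomical, with functional features breaking
ties. PCA components are fit on ICs pooled across both groups so the
reduction cannot encode group membership.

A cluster enters the spectral statistics only if it contains ICs from at
least 70% of unique subjects (a subject with several ICs in a cluster
counts once, and those ICs are averaged within subject before any group
statistic, so no subject is double-counted).

## 4. Effective connectivity

Connectivity uses the top 10 ICs per subject (by explained variance) on
correct incongruent trials only, at 100 Hz.

**Model order.** The parameters-to-data rule requires
(K²p + 1)/(N_s·N_t) ≤ 0.1, evaluated in exact integer arithmetic
(10·(K²p+1) ≤ N_s·N_t). For 10 ICs, 1-s windows (100 samples) and 140
trials the largest admissible order is 13. By default the pipeline fits
the largest admissible order.

**Estimator.** Each 1-s window (advanced in 20 ms steps → 150 positions
over a 4-s epoch; same ms-domain counting as ERSP) is mean-removed per
channel and trial and fit with the Vieira–Morf algorithm: a multichannel
Burg lattice whose reflection coefficients use the geometric-mean
normalization ρ = S_f⁻¹ R_fb S_b⁻ᵀ of the forward/backward prediction
error covariances. This keeps fits stable by construction and behaves
well on short windows pooled across trials. Residual covariance comes
from the final forward residuals; the estimator covariance of the
coefficients uses the inverse regressor covariance from the same window
(lag-major blocks), scaled by Σ_ii/n_eff.

**rPDC.** Directed influence j→i at frequency φ = f/f_s is renormalized
partial directed coherence: with Q(φ) = (Re Ā_ij, Im Ā_ij)ᵀ,
Ā_ij(φ) = −Σ_r a_ij(r)e^(−i2πφr), and V(φ) the 2×2 covariance of Q
induced by the coefficient covariance, rPDC = Qᵀ V⁻¹ Q. Evaluated on 30
log-spaced frequencies from 2 to 49 Hz. Properties the tests pin down:
a truly zero coefficient vector gives exactly 0; rPDC is invariant to
channel rescaling (≤1% at realistic sample sizes); planted directions
separate from their reverses by well over 5×. Numerically singular V is
ridge-regularized by 10⁻¹² of its trace.

## 5. Dipole-density ROI projection

Subject dipole locations vary, so IC-pair connectivity is projected onto
a fixed parcellation through probabilistic dipole densities: each dipole
becomes an isotropic 3-D Gaussian (FWHM 20 mm) evaluated at voxel
centers and truncated at 3σ — a 25.5 mm radius retaining
χ²₃(9) ≈ 97.1% of the mass. Mass on unlabeled (non-brain) voxels is
discarded and the remainder renormalized to 1. Per-ROI weights are the
summed mass inside each label.

The ROI edge value is the **mass-weighted mean** of rPDC over ordered IC
pairs: value(R_l, R_f) = Σ_{j≠i} w_j(R_l) w_i(R_f) rPDC_{j→i} / Σ_{j≠i}
w_j(R_l) w_i(R_f); means (not sums) keep ROI values on the rPDC scale,
and the j = i diagonal is excluded from both numerator and denominator.
Edges with zero pair weight are missing (NaN), propagated as such into
group inference. ROIs reached by fewer than 70% of subjects' densities
are excluded.

Any NIfTI integer label volume can be supplied. Because a custom
anatomical atlas cannot be bundled, the package generates a synthetic
76-region parcellation (seeded Voronoi tessellation of a brain-shaped
ellipsoid, 5 mm voxels) for simulation work.

## 6. Cluster-mass permutation inference

Per ROI edge, pixelwise pooled-variance t-tests compare groups on the
(frequency × time) plane; pixels with two-tailed p strictly below 0.01
enter a mask; 4-connected, sign-pure components form clusters whose mass
is the summed t. Family-wise error is controlled by permutation of the
diagnosis labels: **one global relabeling per iteration applied to every
edge**, preserving inter-edge dependence.

Two scopes:

* `across_edge` (default): per iteration the (u+1)-th largest cluster
  mass pooled over all edges is stored (u = 1). Comparing real masses to
  this null bounds the probability of more than u false-positive
  clusters in the whole graph by α (u-FWER).
* `within_edge`: the largest mass of one pre-selected edge per
  iteration (classical single-edge FWER).

**Sign handling.** The default pools cluster-mass magnitudes across both
signs into one null (`sign_mode="pooled"`), so the u-FWER bound applies
to the *total* number of false clusters. The alternative
(`sign_mode="per_sign"`) keeps separate one-tailed positive/negative
nulls at α each; that controls each sign's count separately but lets the
combined false-cluster rate roughly double (measured 0.155 vs. a 0.081
bound over 200 global-null replicates at α = 0.05; pooled measures
0.055). Both modes are available; pooled is the default because the
scientific claim ("which edges differ") is sign-agnostic.

Cluster p-values use the add-one convention
p = (1 + #{null ≥ mass}) / (1 + n_perm), significant iff p ≤ α; with
n_perm = 10000 the smallest attainable p is 1/10001. The permutation
engine is fully vectorized: group sums for all relabelings via matrix
products, per-permutation clustering via a single 3-D labeling with an
in-plane-only structuring element, and k-th-largest extraction via a
lexsort — ~500 permutations × 30 edges × 300 pixels in well under a
second.

## 7. Group statistics

* Sample characterization: pooled-variance t (age, IQ), Yates-corrected
  χ² (df 1) for gender (the reference 35/60 split at 46%/80% male gives
  χ² = 10.31, p ≈ 0.0013).
* Behavior: per condition × measure one-way ANOVA, F with df (1, N−2) —
  algebraically t².
* Spectral power: per retained IC cluster and time window, a MANOVA over
  the four band powers (Wilks' Λ via log-determinants, Rao's F; exact
  for two groups, equal to the Hotelling T² F; df (4, N−q−1), e.g.
  (4, 69) at N = 74) gates per-band follow-up ANOVAs at p < 0.05.
* ANCOVA re-runs group effects controlling one covariate at a time
  (partial F, df (1, N−3)); partial correlations (severity vs. power,
  controlling age) use residual Pearson r with t-based p at df n−3.

All of these delegate the distributional work to scipy/statsmodels; the
tests verify the exact algebraic identities (F = t², Wilks ≡ Hotelling,
closed-form partial r) to 10⁻⁹.

## 8. Reproducibility and limitations

Every stage is driven by a single integer seed; identical configuration
and seed produce byte-identical result bundles. Known limitations:

* The generator's burst-power calibration is approximate (§1); group
  spectral effects should be interpreted through detection, not dB.
* The synthetic parcellation and scalp proxy are geometric stand-ins;
  anatomical claims require a real atlas (supply via
  `project.parcellation_path`) and real scalp topographies.
* The MVAR model assumes within-window stationarity; planted coupling
  changes are smeared across the ~1 s windows overlapping the effect.
* rPDC magnitudes grow with the effective sample count; compare groups
  at matched trial counts (the pipeline restricts to correct
  incongruent trials for both groups for this reason).
* With small cohorts the number of distinct label permutations can fall
  below `n_perm`; the engine warns and samples with replacement.
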