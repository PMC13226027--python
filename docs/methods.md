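# Methods

Definitions and conventions used by `adsuppress`, in pipeline order. Notation:
a trial holds signals `x` of shape (samples × channels) at sampling rate
`fs`; W1 and W2 are the marker-delimited phases `[AD_Start, Qes_Start)` and
`[Qes_Start, AD_End)`.

## Windowing

Analysis windows are 500 ms. Within each phase they are laid either
end-to-end (`nonoverlap`) or with 50 % overlap (`overlap50`, 250 ms hop). Any
marker falling strictly inside a phase (`Qes_End`, `Ans_Start`, `Ans_End`)
restarts the grid at its sample, so no window straddles an experimental
event. Trailing partials are dropped. Channels are z-scored per trial before
analysis; an exactly constant channel is a validation error.

## Detrended fluctuation analysis (DFA)

For a window signal `x` of length `N`, the profile is
`Y(i) = Σ_{k≤i} (x(k) − x̄)`. For each scale `s` in {16, 32, 64, 128} the
profile is split into `Ns = ⌊N/s⌋` disjoint segments from the start; each
segment is detrended by a least-squares line and
`F(s) = sqrt(mean of all squared residuals)`. The Hurst exponent is the slope
of `log2 F(s)` on `log2 s`, with the fit's R² retained. Windows whose F(s)
vanishes at any scale (constant signal) are flagged missing rather than
estimated.

## Multifractal DFA

The q-order fluctuation function uses `2·Ns` segments — the same partition
applied from both ends of the profile, so the trailing remainder is also
covered — and

- `F_q(s) = { mean_ν [F²(ν,s)]^{q/2} }^{1/q}` for `q ≠ 0`,
- `F_0(s) = exp( ½ · mean_ν ln F²(ν,s) )` (log-averaging limit at q → 0).

`h(q)` is the slope of `log2 F_q(s)` vs `log2 s` per q in {−5…5}. A
monofractal signal has h(q) constant in q; the implementation is checked
against the binomial multiplicative cascade, whose generalized Hurst exponent
is known in closed form: `h(q) = 1/q − log2(a^q + (1−a)^q)/q`, with the
q → 0 limit `h(0) = −log2(a(1−a))/2`.
The window-level feature used downstream is h(2); the h(−5) − h(5) spectrum
width is available behind a flag but off by default.

## Fractional-order dynamical network

Per window, the model is `z[k] = A x[k−1] + u[k] + ε[k]` where `z` is the
channelwise Grünwald–Letnikov (GL) fractional derivative

`z_i[k] = Σ_{j=0}^{min(k,J)} c_j(α_i) x_i[k−j]`, `c_0 = 1`,
`c_j = c_{j−1} (j − 1 − α)/j`, truncated at `J = 50` lags; the first `J`
samples of a window are excluded from the regression.

**Order estimation.** Default (`alpha_method="haar"`): α = p/2 where `p` is
the least-squares slope of log2 mean-squared Haar detail energy against
decomposition level (4 levels per 500 ms window). This wavelet estimator is
cheap, but it reads each channel marginally, so strong coupling biases it. Alternative (`alpha_method="regression"`, used for
planted-network recovery studies): each channel is regressed on its own lags
1…J plus every other channel at lag 1; when the coupling matrix has zero
diagonal, the own-lag-1 coefficient equals α exactly (GL c₁ = −α), the
remaining own lags absorb the GL tail, and the cross terms absorb the
coupling.

**Coupling and inputs.** With α fixed, the fit alternates block-exact
minimization of
`½‖Z − A X − U‖²_F + ½λ_r‖A‖²_F + λ_ℓ‖U‖₁`:
(1) ridge solve `A = (Z−U) Xᵀ (X Xᵀ + λ_r I)^{-1}`; (2) since the input
matrix is the identity, the LASSO step is the exact soft-threshold
`u[k] = S_{λ_ℓ}(z[k] − A x[k−1])`. Each block step minimizes the joint
objective exactly, so the objective is non-increasing — asserted on every
fit; the raw residual is additionally monitored (warning only, since the
ridge term can trade residual against ‖A‖). Defaults: λ_r = 0.1 × mean
diagonal of X Xᵀ; λ_ℓ = 3 × 1.4826 × MAD of the initial residual (a robust
3σ rule). Observed excitations can be supplied (`known_u`), in which case
they are subtracted and the LASSO stage is skipped.

**Dominant eigenmode.** Per window, the eigenvector of the largest-modulus
eigenvalue of Â, reduced to permutation-stable scalars: maximum weight,
participation ratio `1/(n Σ w⁴)` (1 = uniformly spread, 1/n = single
channel), and inter-window cosine stability. Ties break deterministically to
the lowest index; real eigenvectors are sign-fixed (largest-magnitude entry
positive).

## Group statistics

The pooled unit is one channel of one trial: its time-averaged exponent over
a phase's windows. Pools are compared per outcome class (success/failure)
with the two-sample Kolmogorov–Smirnov test (asymptotic p-values, SciPy);
per-channel W1-vs-W2 comparisons use window-level exponents of a single
trial, with short channels flagged rather than dropped. P-values are reported
raw, without multiple-testing correction.

## Classification

The trial descriptor has six entries per phase: mean α, variance of α,
eigenmode max weight, participation ratio, eigenvector stability, and h(2);
the default feature mode is the W2 − W1 difference (absolute-W2 and
concatenated modes are available). Evaluation is leave-one-trial-out logistic
regression (L2, fixed C = 1): the standardizer and the model are fit on the
42 training trials only — per-fold scaler statistics are retained so the
no-leakage property is directly assertable — and the held-out trial is
predicted at threshold 0.5. Accuracy, confusion counts, precision/recall, and
ROC/AUC are computed from the pooled out-of-fold probabilities. Degenerate
folds (single-class or zero-variance features) predict the training majority
with a flat probability and are flagged.

## Synthetic cohort

Each generated trial simulates the FODN model itself: channelwise fractional
orders drawn per phase (W1: N(0.55, 0.25²) clipped to [0, 1.3]; successful
W2: interpolated toward N(0.40, 0.10²) by the effect size `effect_delta`),
sparse random coupling rescaled to spectral radius 0.35 after a left-half-
plane shift (the fractional integrator has a pole at zero frequency, so
positive-real-part coupling eigenvalues are explosive), and 2–4 Hz biphasic
spike trains on roughly a third of the channels, attenuated in W2 for
successful trials. `effect_delta = 0` makes the two outcome classes
statistically exchangeable. All generators are deterministic given a seed;
pipeline substreams are derived from the root seed by hashing stream names.

## Validation study sizes

The shipped studies use desk-scale sizes chosen once: Hurst recovery on
fractional Gaussian noise at n = 8192 over 20 seeds per H ∈ {0.3, 0.5, 0.7,
0.9}; the cascade oracle at 2¹⁴ samples with scales 16–1024 (a window-scale
grid this long a series can support; the 500 ms pipeline windows use 16–128);
network recovery with 10 channels × 2000 samples over 10 seeds; KS
calibration with 200 replicate pairs of n = 1000; and the cohort study at 43
trials (20 successes) × 60 channels, with 20 independent null cohorts for the
no-effect control. The null control asserts the mean accuracy across cohort
seeds, not each seed's accuracy: single-cohort leave-one-out accuracy under
exchangeable labels is itself noisy (and typically slightly below the
majority rate, a known artifact of leave-one-out pooling).

For parameter-recovery studies the planted coupling is skew-symmetric
(`random_skew_coupling`): its spectrum is purely imaginary, which is stable
under the fractional integrator for α < 1 even at spectral radius 0.85, and
its zero diagonal is exactly the identifiability condition of the regression
α estimator.
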