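# Methods

`lagcvr` implements an end-to-end analysis linking BOLD cerebrovascular
reactivity (CVR) to baseline cerebral blood flow (bCBF), together with a
synthetic study generator that plants known ground truth so every stage can
be validated without access to raw MRI data.

## Study structure emulated by the generator

Each synthetic subject has five BOLD data segments of equal length (400
volumes at TR 1.2 s; the first 10 volumes of each segment are discarded,
leaving 390 analyzed): a breath-hold task followed by rest (`BH+REST`), a
cued-deep-breathing task followed by rest (`CDB+REST`), and three pure-rest
segments (`REST`, `REST_BH`, `REST_CDB`). The breath-hold block repeats 3
cycles of 24 s paced breathing (3 s IN/OUT cues), a hold, and free-breathing
recovery; cued deep breathing repeats 2 blocks of 8 fast deep breaths (2 s
cues) plus recovery. The hold length is not uniquely determined by the
protocol description we emulate, so it defaults to 15 s (typical for
breath-hold CVR) and is configurable; only relative timing matters for the
recovery tests. The five segments are generated independently with a shared
ground truth; vascular or neural carry-over from a task into the following
rest period is not modeled.

Each segment carries a 1000 Hz capnograph waveform built from raised-cosine
breaths between near-zero inspiratory troughs and end-tidal peaks. Peaks
follow the planted end-tidal program: baseline 38 mmHg (inside the 30–45
mmHg operating range where the CVR dose-response is approximately linear); a
post-hold peak of baseline + 10 mmHg decaying back with an 8 s time
constant; deep-breathing peaks ramping down to baseline − 8 mmHg; and a slow
AR(1) fluctuation (SD 1 mmHg per breath) during rest and paced breathing —
the natural variability that rest-only CVR modeling has to rely on.
Measurement noise (SD 0.2 mmHg) perturbs only the realized peaks; the
noiseless program is retained as ground truth. Single-sample breath maxima
make end-tidal detection exact at zero noise, which is what lets
forward/inverse closure tests demand float-precision recovery.

The BOLD forward model mirrors the analysis GLM: voxel series =
mean · (1 + amp/100 · x(lag)) + drift + motion-coupled term + structured
low-frequency components + white noise, where x(lag) is the HRF-convolved,
baseline-subtracted end-tidal regressor shifted by the voxel's planted lag —
produced by the *same* code path the analysis uses. Planted fields are
spatially smooth: CVR amplitude 0.25 ± 0.06 %BOLD/mmHg clipped to
[0.1, 0.4], lags SD 3 s clipped to ±9 s and snapped to the 0.3 s grid, mean
signal 1000 ± 10%. Drift lives on the same orthonormal polynomial basis the
GLM removes and is demeaned over the analyzed window so the fitted intercept
is exactly the voxel mean; the motion nuisance is a random walk with
voxelwise coupling (~0.1% of mean). Three spatially smooth 0.01–0.1 Hz
components totalling 0.2% of the mean signal model structured physiological
fluctuations; unlike white noise they do not average away over parcels,
which is the mechanism that degrades rest-segment CVR–CBF coupling at the
parcel level. Thermal noise is set by the target temporal SNR (default 50).

CBF ground truth is planted at the parcel level: parcel means are coupled to
the CVR-amplitude parcel means at a target *Spearman* correlation (default
0.6) via a normal-scores mixture — the base values are rank-transformed to
Gaussian scores and mixed with an orthogonalized Gaussian residual at
Pearson level `2·sin(πρ/6)`, the bivariate-normal level whose grade
correlation equals ρ. This makes the planted rank coupling independent of
the base field's marginal distribution, and ρ = 1 degenerates to identical
ranks. Parcel values (60 ± 15 ml/100 g/min) are broadcast to voxels with
smooth zero-mean within-parcel variation.

The atlas is an ellipsoidal "brain" split into left/right hemispheres, each
partitioned into 48 near-equal-count parcels (96 total) by successive
equal-count slicing along x, y, z — guaranteeing no parcel is empty on any
grid large enough. Default grid 24×24×12 voxels at 2 mm, small enough that
a full 101-lag, five-segment study runs in seconds per subject.

The pCASL series is 11 tag + 11 control volumes (tag first) plus a final M0
volume; control − tag differences equal the forward single-compartment
kinetic model evaluated at the planted CBF, plus optional Gaussian noise.

## End-tidal regressors

End-tidal peaks are detected with a minimum breath separation (2 s) and
prominence (3 mmHg); linear interpolation between peaks defines the
continuous end-tidal tide curve. The baseline is the mean end-tidal value
over the rest portion of the acquisition (configurable window); the
regressor is the tide minus baseline. The canonical HRF is the conventional
double-gamma (response gamma shape 6, undershoot shape 16, ratio 1/6, 32 s
support). The kernel is returned with unit peak — so sampled kernels agree
across sampling rates — and the convolution divides by the kernel sum,
giving exactly unit steady-state gain: a sustained 1 mmHg end-tidal change
produces a regressor change of 1 mmHg, keeping CVR in %BOLD/mmHg. The
convolved regressor is shifted over a symmetric grid (±15 s in 0.3 s steps,
101 lags including 0) and sampled at the analyzed volume times by linear
interpolation (the signal is already low-pass after convolution). Positive
lag delays the regressor relative to the BOLD series. Edge effects are
handled by holding the first/last end-tidal value; rows that needed the held
edge are flagged.

## CVR mapping

The design per segment is intercept + orthonormal polynomial drift (one
order per 150 s of scan) + six demeaned motion parameters + the CO2
regressor (not demeaned, so the intercept estimates the voxel's baseline
signal). No-Opt CVR is `100 · β_CO2 / β_intercept` from the lag-0 model.
Lag-Opt refits the model once per lag and keeps, per voxel, the lag with the
largest full-model R²; ties break to the smallest |lag|, negative before
positive, making results independent of evaluation order. Winning lags at
the grid edge are flagged (censoring is available but off by default).
Voxels whose fitted mean falls below 1e-6 of the mean absolute signal get
NaN CVR plus a flag rather than a division blow-up. Fits are ordinary least
squares via thin QR, vectorized over voxels; voxel independence makes the
computation embarrassingly parallel and execution-order invariant.

### Recovery limits at realistic noise

At zero noise the pipeline recovers planted amplitudes to float precision
and planted on-grid lags exactly (forward and inverse share the regressor
code). At realistic noise the precision is bounded by the information in the
regressor itself: for a breath-hold segment with a 10 mmHg end-tidal rise,
390 volumes and temporal SNR 50, the nuisance-residualized regressor norm
(~44) and its lag-derivative norm (~6.6 s⁻¹) give lower bounds of roughly
18% SD on relative amplitude and ~1.2 s SD on lag per voxel at the median
planted amplitude. The estimator attains these floors (observed medians:
~14% amplitude error, ~0.9 s lag error; signed errors centered on zero), so
per-voxel sub-grid (0.3 s) lag accuracy at this SNR is not achievable from a
single breath-hold run — a property of the measurement, not of the
implementation. Parcel averaging and group statistics, not voxel precision,
carry the downstream analyses.

## Baseline CBF

Quantification uses the consensus single-PLD closed form

    CBF = 6000 λ ΔM exp(PLD/T1b) / (2 α T1b M0 (1 − exp(−τ/T1b)))

with λ = 0.9 ml/g, α = 0.85, τ = 1.8 s, PLD = 1.8 s (inflow 3.6 s) and
blood T1 1.65 s; the tissue T1 (1.3 s) used by Bayesian kinetic fits is kept
in `AslParams` as metadata. This transparent closed form replaces Bayesian
variational inversion with adaptive spatial priors; the optional substitute
for spatial regularization is fixed-FWHM Gaussian smoothing with mask-aware
edge renormalization, recorded in output metadata. Voxels with non-positive
M0 are excluded and flagged. Single-PLD acquisition means no arterial
arrival-time estimation and no partial-volume correction.

## Resting-state metrics

Per voxel, after least-squares quadratic detrending (the original mean is
retained): ALFF is the mean one-sided Fourier amplitude in 0.01–0.1 Hz;
fALFF divides the in-band amplitude sum by the full non-DC amplitude sum
(mean vs sum conventions differ across implementations; ours affects scale
only, never rank correlations); RSFA is the SD of the ideal-bandpassed
series and mRSFA normalizes it by the voxel mean. The bandpass is an ideal
spectral mask (exact in tests, at the price of Gibbs ringing on non-bin
components). Smoothing, when requested (default 4 mm FWHM, double the voxel
size), is applied to the 4-D data before metrics; smoothed and unsmoothed
variants are always both produced because parcel correlations of ALFF/mRSFA
with perfusion are sensitive to this step.

## Parcel statistics

Between subjects: Pearson correlation of per-subject gray-matter medians,
reported with and without influential subjects removed, where influence is
Cook's distance > 4/n on the bivariate fit, computed once (single pass —
iterative screening at n = 9 is unstable). Results are reported uncorrected
and Benjamini–Hochberg-corrected across the 10 segment × scheme tests.
Within subject: Spearman correlation across the 96 parcel means; outlier
parcels are screened by Cook's distance > 4/n on the rank-rank regression
(ranks, for consistency with the rank correlation) in one pass. Significance
uses Fisher Z: `atanh(ρ)·√(n_used − 3)` against the two-tailed normal
quantile (1.96 at α = 0.05); removing parcels lowers n_used and raises the
|ρ| needed, which is reported as the adjusted critical value. Ties receive
average ranks.

## Group inference

The 2 (scheme) × 5 (segment) within-subject design is tested with classical
repeated-measures F statistics (separate subject×factor error strata) whose
null distributions come from permutations rather than normality or
sphericity assumptions: scheme labels are permuted within each
subject × segment stratum, segment labels within each subject × scheme
stratum, and the full cell vector within subject for the interaction. Each
scheme is exact under its exchangeability null, and the main-effect schemes
remain valid in the presence of the other main effect. p-values use the
add-one estimator; when a stratified permutation group is smaller than the
requested count the test enumerates it exhaustively and says so. The default
is 100,000 permutations; tests and the acceptance script use 2,000 for
runtime, which changes p-value granularity, not validity. Simple main
effects are all pairwise level contrasts via within-subject sign-flip
permutation (exhaustive when 2^S fits the budget) or a paired t-test,
FDR-corrected. Extreme outliers are values beyond 3×IQR of their design
cell (type-7 linear-interpolation quartiles — the convention matters at
S = 9 and is logged); three sensitivity variants are run: full data, flagged
subjects removed, flagged values replaced by the mean of the cell's
remaining values.

## What the synthetic world does and does not show

Passing tests demonstrate that the estimators are unbiased and exact where
they should be, that the statistics are calibrated (type-I error of the
permutation ANOVA, Pearson null rates), and that the qualitative orderings
the analysis is designed to detect (task > rest coupling, lag optimization
helping on task data) emerge for the planted mechanisms. The generator does
not simulate MR physics, motion-induced resampling, distortion,
task-to-rest carry-over, arterial transit heterogeneity, or neurovascular
confounds beyond smooth low-frequency components — so passing tests do not
certify performance on real data with those features; they certify the
arithmetic and the statistical machinery.

## Numerical conventions

0-based voxel indexing; world coordinates only through the affine. OLS via
thin QR; R² about the mean, clipped to [0, 1]; all-zero series yield zero
betas and R² 0. Degenerate 0/0 F ratios report F = 0 with a warning.
Seeds: every stochastic routine takes an explicit seed or Generator;
identical seeds give bit-identical outputs. Problem sizes used by the test
suite and acceptance script (grids 12–24 voxels across, 3–20 subjects,
2,000 permutations, 200–500 Monte-Carlo replicates) were chosen as the
smallest sizes at which the tested quantities are stable.
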