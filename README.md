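# lagcvr

Toolkit for studying how BOLD cerebrovascular reactivity (CVR) relates to
baseline cerebral blood flow (bCBF), built for fMRI researchers who map CVR
with breathing tasks and end-tidal CO₂ recordings.

CVR is modeled voxelwise with a lagged general linear model: the end-tidal
CO₂ trace (P_ET_CO₂) is peak-detected, convolved with a canonical
double-gamma HRF, shifted ±15 s in 0.3 s steps, and down-sampled to the TR.
The model per voxel is

    y(t) = β₀ + drift + motion + β_CO₂ · x_lag(t) + ε,

and CVR = 100·β_CO₂/β₀ in %BOLD/mmHg — either from the unshifted regressor
(**No-Opt**) or from the lag maximizing full-model R² (**Lag-Opt**). Baseline
CBF comes from single-PLD pCASL (11 tag/control pairs + M0) through the
consensus closed-form quantification, in ml/100 g/min. Resting-state
amplitude metrics (ALFF, fALFF, mRSFA; 0.01–0.1 Hz) are computed from the
rest segments. The statistics layer provides between-subject Pearson
correlations with Cook's-distance (4/n) influence screening, within-subject
Spearman correlations across 96 cortical parcels with Fisher-Z significance
(critical value 1.96 at α = 0.05, adjusted when parcels are removed), and a
permutation repeated-measures ANOVA (scheme × data segment) with FDR-corrected
contrasts and 3×IQR extreme-outlier sensitivity reruns.

Because raw studies of this kind are rarely shareable, the package includes a
first-class synthetic study generator (`lagcvr.synthetic_world`) that plants
ground-truth CVR amplitude, hemodynamic lag and CBF fields with a known
parcelwise coupling, and emulates the full acquisition: five 390-volume data
segments (breath-hold, cued deep breathing, and three rest segments), 1000 Hz
capnograph traces, motion tables, pCASL series, atlas and gray-matter mask.
See `docs/methods.md` for the model and its limits.

## Worked example

```python
from lagcvr.io_core import StudyConfig
from lagcvr.pipeline import run_pipeline

cfg = StudyConfig(n_subjects=4, n_perm=2000, seed=11, grid_shape=(16, 16, 8))
report = run_pipeline(cfg)

cvr = report.spatial[report.spatial.metric == "cvr_amp"]
print(cvr.groupby(["segment", "scheme"]).rho.mean().round(3))
print(f"scheme effect: F={report.anova.f_a:.2f}, p={report.anova.p_a:.4f}")
```

Output:

```
segment   scheme
BH+REST   Lag-Opt    0.600
          No-Opt     0.554
CDB+REST  Lag-Opt    0.476
          No-Opt     0.479
REST      Lag-Opt    0.209
          No-Opt     0.366
REST_BH   Lag-Opt    0.172
          No-Opt     0.336
REST_CDB  Lag-Opt    0.243
          No-Opt     0.334
scheme effect: F=3.41, p=0.1619
```

Each number is the mean (over simulated subjects) Spearman correlation
between parcelwise CVR and planted CBF. The planted coupling is 0.6: the
breath-hold segment nearly recovers it and lag optimization helps there,
while rest-only segments — whose end-tidal fluctuations are small relative
to intrinsic low-frequency signal — couple far more weakly, and lag
optimization on noise-dominated rest data hurts. The ANOVA F is the
repeated-measures scheme main effect across all five segments with its
permutation p-value.

The same stages are scriptable from the shell:

```bash
lagcvr simulate --out study/ --subjects 2 --seed 1
lagcvr petco2 --trace study/sub-00/co2_BH_REST.tsv --n-volumes 400 --out reg.tsv
lagcvr cvr --bold study/sub-00/bold_BH_REST.nii.gz --mask study/sub-00/gm_mask.nii.gz \
           --regressors reg.tsv --optimize lag --out-prefix sub00_bh
lagcvr cbf --asl study/sub-00/pcasl.nii.gz --m0-index 22 --out sub00_cbf.nii.gz
lagcvr run --out report/ --subjects 4 --seed 11
```

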