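# dibh-margin

Tools for quantifying chest-wall positioning errors during **deep
inspiration breath-hold (DIBH)** breast radiotherapy and turning them into
a planning target volume (PTV) margin.

During DIBH delivery, the electronic portal imaging device records a
continuous (cine) stream of MV frames. The chest wall appears as a strong
lung/soft-tissue intensity step; its position in every frame, measured
against the reference position from the planning DRR, gives one signed
error per frame. Pooling those errors over patients, fractions and frames,
the package answers the clinical question: *how much margin does the
chest-wall target need along the measurement direction?*

The package is for medical-physics and radiotherapy researchers who want
to run, or stress-test, this error-decomposition pipeline without access
to clinical cine EPID archives — every stage is driven by a seeded
synthetic generator with known ground truth.

## Model

Frame-level errors follow a nested random-effect model

```
y[p,f,k] = M + a[p] + b[p,f] + e[p,f,k]
a ~ N(0, Σ²pt),  b ~ N(0, σ²fr),  e ~ N(0, σ²intra)
```

where `M` is the overall mean, `Σpt` the inter-patient SD, `σfr` the
inter-fraction SD (fractions are nested in patients) and `σintra` the
intra-fraction SD. Components are estimated by **REML** (the design is
unbalanced: frame counts differ per field), with profile-likelihood
confidence intervals. For `N` fractions the inter-fraction variance is
split between the systematic and random pools,

```
Σ²eff = Σ²pt + σ²fr / N
σ²eff = (1 − 1/N) σ²fr + σ²intra
```

and the one-dimensional PTV margin follows the van Herk recipe
`2.5 Σeff + 0.7 σeff` (95% minimum CTV dose for 90% of patients).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each writes its tables under `results/`):

```bash
python analysis/01_simulate_cohort.py      # 25 patients x 16 fractions x 2 fields
python analysis/02_track_frames.py         # render frames, track the edge
python analysis/03_fit_variance_components.py
python analysis/04_ptv_margin.py
```

With the default seed the cohort has 310,301 frames and the fit prints

```
Component                               mm  95% CI (mm)
Inter-patient SD (Sigma_pt)           0.79  0.58 to 1.12
Inter-fraction SD (sigma_fr)          1.25  1.17 to 1.35
Intra-fraction SD (sigma_intra)       1.63  1.63 to 1.64
Overall mean (M)                      0.17  -0.16 to 0.50
```

recovering the generating values (0.82, 1.19, 1.63, 0.30) mm within
Monte-Carlo scatter — the inter-patient interval is widest because only 25
patients inform it, while ~3·10⁵ residual degrees of freedom pin `σintra`.
The margin step then prints

```
Effective errors at N = 16
  Systematic (Sigma_eff)                0.85
  Random (sigma_eff)                    2.03
PTV margin (2.5 Sigma_eff + 0.7 sigma_eff)    3.55
```

i.e. a ~3.6 mm one-dimensional margin on the beam's-eye-view plane. The
edge tracker itself is validated on a static synthetic phantom stack
(per-frame scatter 0.012 px, well under the 1-pixel criterion) and on
stacks with known motion (round-trip RMSE ≪ 1 isocenter pixel).

The same stages are available as a CLI (`dibh-margin simulate | track |
fit | margin | pipeline`) configured by a single YAML file, and as plain
library calls:

```python
from dibh_margin import SimulationSpec, simulate_errors, fit_reml, margin_report

fit = fit_reml(simulate_errors(SimulationSpec(seed=1)))
print(margin_report(fit, n_fractions=16).table())
```

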