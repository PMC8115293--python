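# ecmquant

Quantification pipelines for assays that link dermal extracellular-matrix
(ECM) remodelling to melanoma invasion. UVR-damaged fibroblasts secrete
collagenases (notably MMP1) that degrade dermal collagen; degraded, less
aligned matrices restrain tumour-cell invasion. Testing that idea requires
quantitative readouts from several very different assays, and this package
implements the full measurement chain for each of them:

| stage | readout |
| --- | --- |
| `ecmquant.spheroid` | invasive area % of a tumour spheroid and count of individually invading nuclei, from Hoechst z-stacks |
| `ecmquant.fibres` | per-pixel fibre orientation (structure tensor) and the fraction of fibres within 10° of the mode |
| `ecmquant.degradation` | DQ-collagen degraded area per cell, low/medium/high ring scoring with the weighted H-score, SHG mean intensity, AFM Rq roughness |
| `ecmquant.scores` | 2^−ΔCt relative expression, geometric-mean signature scores, median splits, histology binarisation, Kaplan–Meier/log-rank plumbing |
| `ecmquant.synthgen` | synthetic fixtures for all of the above with machine-readable ground truth |

The core statistics, in the field's notation:

- invasive area percentage: `100·|invasion| / (|core| + |invasion|)` from a
  layered core/invasion mask of the projected nuclear channel;
- aligned fraction: mass of the axial orientation distribution within ±10°
  of its mode (period 180°);
- degradation H-score: `H = (1·n_low + 2·n_medium + 3·n_high) / n_total`,
  classes defined by the peri-cytoplasmic ring width relative to the
  cytoplasmic diameter (<1/4, ~1/3, ~1/2); conditions compared as H ratios;
- AFM roughness: `Rq = sqrt(mean((z − mean z)²))`;
- signature score: per-sample geometric mean of signature-gene expression on
  the log2(x+1) scale, split at the cohort median;
- relative expression: `2^−ΔCt` against the geometric mean of housekeeping
  genes.

Every stage is validated against synthetic data with planted ground truth
(see `docs/methods.md` for models, parameters, and limitations).

## Worked example

Run the end-to-end synthetic demo (any fixed seed is byte-reproducible):

```sh
ecmquant demo --seed 7 --out-dir demo_out
```

```
ecmquant demo (seed=7)

[spheroid invasion]
  scale= 1.0: invasive_area= 31.17% (truth  33.47%), single cells=20 (truth 20)
  scale= 0.5: invasive_area= 18.67% (truth  20.53%), single cells=10 (truth 10)
  scale= 0.1: invasive_area=  2.27% (truth   4.98%), single cells=2 (truth 2)
  invasion decreases with matrix degradation: True

[fibre alignment]
  kappa= 0.0: mode= -21.5 deg, aligned_fraction=0.1636
  kappa= 4.0: mode=  31.5 deg, aligned_fraction=0.5417

[collagen degradation]
   control: n=(34,22,4) H=1.500
        uv: n=(8,16,36) H=2.467
  degradation ratio uv/control = 1.644

[surface roughness]
   constant (A=3.0): Rq=0.0000 (analytic 0.0000)
  two_level (A=2.0): Rq=2.0000 (analytic 2.0000)
   sinusoid (A=2.0): Rq=1.4142 (analytic 1.4142)

[signature survival]
  n=200, planted hazard ratio=2.0
  median-split agreement with truth: 1.000
  log-rank statistic=26.383, p=2.800e-07
```

Reading the report: scaling the planted invading cells down (emulating a
collagenase-degraded matrix) lowers both the measured invasive area and the
single-cell count; a fibre field with higher orientation concentration
(κ = 4 vs 0) has a much larger aligned fraction around its planted 30° mode;
a strongly degrading "uv" condition scores a higher H than the control and
their ratio summarises the change; the roughness closed forms are met; and
the cohort whose planted high-score half carries a hazard ratio of 2 is
cleanly separated by the median split (log-rank p ≈ 3·10⁻⁷).

The same stages are available as subcommands on files
(`ecmquant spheroid quantify`, `ecmquant fibres analyze`,
`ecmquant degradation score|rq`, `ecmquant scores maf`, `ecmquant synth`),
and as a library:

```python
from ecmquant import synthgen
from ecmquant.spheroid import quantify_spheroid

spec = synthgen.SpheroidSpec(seed=1)
stack, truth = synthgen.make_spheroid_image(spec)
metrics, seg = quantify_spheroid(stack)
print(metrics.invasive_area_pct, truth.invasive_area_pct)  # 31.37 32.88
```

## Analysis scripts

`analysis/01…05_*.py` are thin numbered drivers that run each stage on
synthetic benchmarks and write tables under `results/` (images under
`scratch/`): benchmark generation, spheroid recovery and dose response,
fibre alignment series, degradation H-scores and roughness, and signature
survival separation. Each prints what it found; run e.g.
`python analysis/02_spheroid_invasion.py --seed 3`.

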