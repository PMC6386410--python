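# ecogdac

Distance-averaged correlation and spatially coherent component analysis for
micro-ECoG electrode grids.

## The problem

Dense electrocorticography grids (sub-millimetre pitch) record local field
potentials that are strongly correlated between neighboring electrodes.  How
that correlation falls off with inter-electrode distance — and *why* — is
what decides how closely electrodes are worth packing.  `ecogdac` is for
electrophysiologists and electrode designers who want to:

1. measure the **distance-averaged correlation (DAC)**: the mean Pearson
   correlation between all equidistant electrode pairs, pooled over short
   analysis windows, per frequency band;
2. explain it with a **Gaussian spatial-component forward model**: latent
   components with circular 2D Gaussian weight profiles
   `W[i,j] = A_j exp(-d(i,j)² / 2σ_j²)`, for which the channel covariance is
   exactly `Σ = WWᵀ` and, in the dense-component limit, the correlation is a
   Gaussian of distance with standard deviation `√2·σ`.  Per-channel noise
   ε enters on the diagonal and a common reference ρ everywhere:
   `r'_{ij} = (Σ_{ij} + εδ_{ij} + ρ) / √((Σ_{ii}+ε+ρ)(Σ_{jj}+ε+ρ))`;
3. attribute the measured DAC to individual **ICA/PCA components**: any
   decomposition `s = Wz` normalized so components are uncorrelated with
   unit variance satisfies `cov(s) = WWᵀ`, so each component contributes a
   rank-1 *reduced covariance* `Σᶜ = w_c w_cᵀ` and a reduced correlation
   (full-covariance denominator) whose distance averages sum exactly to the
   full DAC; the *drop* a component explains is its curve minus its
   zero-distance value;
4. characterize component weight maps with bounded least-squares **circular
   2D Gaussian fits** `A·exp(-((x-B)²+(y-C)²)/2D²)+E`, summarizing spatial
   coherence by R² and width D, with bootstrap CIs on the median width; and
5. handle **common average referencing** as explicit matrix algebra
   (`C = I − J/N`), which recenters every component map to zero mean and
   annihilates reference-like uniform components.

Everything runs end-to-end on synthetic multichannel recordings with known
ground truth (band-limited bursty sources, Gaussian spatial weights,
channel noise, common reference), so the whole chain is testable without
any recording hardware.

## Worked example

```python
import numpy as np
from ecogdac import (five_source_study_spec, generate_recording,
                     build_distance_structure, decompose_window,
                     reduced_dac, fit_component_map)

spec = five_source_study_spec(seed=1)        # 56 ch @ 0.4 mm, 5 sources
rec, W_true = generate_recording(spec)       # 20 s @ 500 S/s + ground truth
ds = build_distance_structure(spec.grid)

mm = decompose_window(rec.data, method="ica", n_keep=5, seed=0)
contrib = reduced_dac(mm, ds)
for c in range(3):
    f = fit_component_map(mm.weights[:, c], spec.grid)
    print(f"component {c}: R²={f.r_squared:.3f} width={f.width:.2f} pitches "
          f"drop={contrib.percent_dac_drop[c]:.1f}%")
```

prints

```
component 0: R²=0.993 width=1.50 pitches drop=23.5%
component 1: R²=0.997 width=1.54 pitches drop=22.6%
component 2: R²=0.998 width=1.52 pitches drop=22.7%
```

i.e. the leading ICA components are almost perfectly circular-Gaussian with
fitted widths matching the generating source width (1.5 pitches), and each
explains a large share of the fall-off of correlation with distance.

The same pipeline is scriptable from the shell:

```bash
ecogdac synth --seed 1 --out demo
ecogdac dac --recording demo/recording.h5 --geometry demo/geometry.json \
        --band 20-30 --out demo/dac.csv
ecogdac model-study --sigmas 1.5,2,3,4 --iterations 200 --out model
```

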