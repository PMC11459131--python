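# tiplink

Analysis of optical-trap force-ramp experiments on dimeric tip-link
cadherins — in particular protocadherin 15 (PCDH15), the protein that,
together with cadherin 23 (CDH23), forms the tip link conveying sound-evoked
force to the mechanotransduction channels of cochlear hair cells.  The
package is aimed at single-molecule biophysicists who record repeated
extension–relaxation cycles on one tethered molecule and want to turn those
trajectories into mechanical parameters, unfolding statistics,
conformational states and refolding probabilities.

## The model

A force-ramp cycle raises the applied force at a constant rate from a 1 pN
rest to a peak and back, with a 2 s rest before the next cycle.  The
end-to-end distance *x* of the tethered dimer at force *F* is described by a
saturating entropic term plus a linear (enthalpic) spring:

```
x(F) = x_E / (1 + F_half / F) + F / K
```

* **x_E** — maximal entropic extension (nm): length gained by straightening
  thermal undulations, interdomain linkers and any unfolded polypeptide;
* **F_half** — force at which the entropic extension is half complete (pN);
* **K** — enthalpic (Hookean) stiffness (pN/nm ≡ mN/m), read from the
  inverse slope of the extension–force relation above 30 pN.

Sudden steps in *x* during a ramp are unfolding events.  The pipeline
detects them, cuts each phase into segments at the events, fits the model to
every segment (one shared F_half per phase, K fixed from the high-force
slope), clusters the pooled relaxation-phase x_E values into six
conformational states by 1-D k-means, assigns every segment to a state by
k-nearest-neighbour classification (k = 3), and derives interstate
transition maps, occupancy, per-state entropic stiffness versus force, and
the percentage of cycles that refold fully (a cycle that reached a state
beyond the folded pair and whose successor starts back in a folded state).

Because the raw laboratory recordings are not bundled, the package includes
a first-class synthetic-data generator: Bell–Evans unfolding kinetics on a
ladder of structural units (independent linkers plus a sequential domain
chain with zip-back refolding) superimposed on the saturation-spring
mechanics, with presets for wild-type and deafness-mutant (V507D) dimers at
saturating (3 mM), physiological (20 µM) and zero (EDTA) Ca²⁺.

## Worked example

```python
import numpy as np
from tiplink import SaturationSpring, extension_at_force, FitParams
from tiplink.simulate import simulate_all_presets
from tiplink.pipeline import analyze_datasets

# fit the mechanical model to one noisy force-extension phase
f = np.linspace(1, 60, 600)
x = extension_at_force(FitParams(63.8, 2.4, 2.5), f) \
    + np.random.default_rng(0).normal(0, 0.3, 600)
res = SaturationSpring(f, x, k_enthalpic=2.5).fit()
print(res.summary())

# full pipeline on the six synthetic condition presets
datasets = simulate_all_presets(n_cycles=100, seed=1)
result = analyze_datasets(datasets)
print("state means (nm):", np.round(result.state_model.means, 1))
print(result.refolding_table().round(1).to_string(index=False))
```

prints

```
Saturation-spring model fit
============================================
n samples                                600
force span (pN)                       59.000
K fixed (pN/nm)                        2.500
--------------------------------------------
x_E (nm)             63.7811        0.0216  (SE)
F_half (pN)           2.3958        0.0067  (SE)
--------------------------------------------
resid RMS (nm)                        0.2989
R^2                                  0.99950

state means (nm): [ 46.5  76.6 106.9 121.  127.3 198.1]
construct  calcium  percent_full_refolding  sem  n_datasets
    V507D 0 M EDTA                    42.3  0.0           1
    V507D    20 uM                    58.2  0.0           1
    V507D     3 mM                    82.7  0.0           1
wild-type 0 M EDTA                    63.3  0.0           1
wild-type    20 uM                    87.5  0.0           1
wild-type     3 mM                     NaN  NaN           1
```

The fit recovers the generating parameters (x_E = 63.8 nm, F_half = 2.4 pN)
to well within their standard errors.  The six state means step up by the
linker span (~12.5 nm) and then by domain-scale gains (~30, ~18, ~72 nm).
The refolding table mirrors the structure of the study's summary: refolding
worsens as Ca²⁺ falls and with the V507D mutation, and the wild type at
saturating Ca²⁺ never leaves the folded states, so its entry is undefined
(NaN).

The closed-form spring calculus is exposed directly:

```python
from tiplink import series_stiffness, scaled_stiffness
k_cdh23 = scaled_stiffness(6.4, 2.3)       # 2.78 mN/m
k_tl = series_stiffness(6.4, k_cdh23)      # 1.94 mN/m — the tip-link stiffness
```

A thin CLI wraps the library: `tiplink simulate`, `tiplink detect`,
`tiplink analyze` and `tiplink report --config cfg.json --seed 1 --out out/`
(the report bundle contains all tables plus a manifest that reproduces them
exactly).

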