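# sfsmac

Motion-artifact detection and correction for single-fiber spectroscopy
(SFS) recordings of brain hemodynamics, with a Monte Carlo
photon-transport simulator and a synthetic-data generator for validating
the pipeline end to end.

## The problem

A single multimode fiber (400 μm core, NA 0.53, 16°-polished tip)
implanted in a deep brain region both delivers broadband light and
collects the backscatter `Ib(t, λ)`, resolved by a spectrometer at
~10 Hz.  Reflectance is normalized between glycerine and air references,

    R(t, λ) = (Ib − Ig) / (Ia − Ig),

and the 545 nm channel (a hemoglobin isosbestic wavelength with strong
absorption) tracks blood perfusion.  When a freely moving animal jerks
the fiber, optical coupling along the light path changes abruptly,
producing broadband step-like intensity shifts that masquerade as
hemodynamic events.

The package implements three linked ideas:

1. **A hemodynamics-insensitive band.**  Photon-transport simulation
   shows collected light at 670–680 nm is an order of magnitude less
   sensitive to blood absorption than at 545 nm, so variation there is
   dominated by motion.  The *dissimilarity metric*
   `DM(i) = (S(i) − M(i)) / M(i)` — band-summed intensity `S` against its
   1 s window mean `M` — and its standard deviation σ_DM quantify
   artifact magnitude, exactly invariant to detector gain.
2. **A mechanistic artifact model.**  Artifacts are modelled as
   transmission changes at the fiber/brain interface: a coating with
   transmission τ scales the detected tissue return by τ² (two interface
   crossings) and shifts the whole reflectance spectrum, reproducing the
   offset-like shifts seen in vivo.
3. **Motion-artifact correction (MAC).**  The zero-mean band series
   `n̂(t)` proxies all transmission changes; each wavelength channel is
   corrected as `Ic(λ, t) = I(λ, t) − m(λ)·n̂(t)` with `m(λ)` an OLS
   slope.  `MotionArtifactCorrector` is a scikit-learn transformer;
   `fit_mac`/`apply_mac` wrap it for spectral frames.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Generate the dynamic validation experiment (7 s at 10 Hz, stimulus on
2–4 s, a 96% transmission artifact on 2–3.5 s) and correct it:

```python
import numpy as np
from sfsmac import (ArtifactSchedule, HemodynamicModel,
                    generate_dynamic_dataset, figure4_experiment)

ds = generate_dynamic_dataset(
    HemodynamicModel(), ArtifactSchedule.paper_default(),
    n_photons=500_000, seed=1, independent_reference=True,
)
rep = figure4_experiment(ds)
for name, mse in [("corrupted", rep.mse_corrupted_vs_ideal),
                  ("corrected", rep.mse_corrected_vs_ideal)]:
    print(name, "region MSE:", np.round(mse, 6))
```

prints (seed 1):

```
corrupted region MSE: [2.000000e-06 4.998608e+01 3.750000e-04]
corrected region MSE: [7.000000e-06 1.800551e+00 1.846000e-03]
```

Reading: region 2 (1.8–3.6 s, during the artifact) of the corrupted
545 nm percent-change trace sits ~5 orders of magnitude above the
artifact-free regions 1 and 3; applying MAC drops it by a factor ~27
(~1.4 orders) while leaving the artifact-free regions at the simulation
noise floor — the artifact is removed, the stimulus-evoked perfusion
response survives.

The same experiments are scriptable from the shell:

```bash
sfsmac mc-sensitivity --seed 1 --fidelity ci --out sens.json
sfsmac figure4 --seed 1 --fidelity ci --out fig4.json
sfsmac run-paper-sims --seed 1 --fidelity paper --outdir out/
```

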