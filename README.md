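# acuitysim

Template-matching simulation of letter acuity under static and temporally
fluctuating optical defocus.

## The problem

The optical defocus of the human eye is rarely steady: accommodative
microfluctuations swing it by ~0.3 D at frequencies below 2 Hz, and in the
binocular-vision dysfunction called spasm of the near reflex the swings reach
1.5–2.5 D. How much letter acuity is lost to a sinusoidal defocus of
amplitude *A* (diopters) and frequency *f* (Hz) — and what decision strategy
lets the visual system limit that loss — is the question this package
simulates.

The core is an image-computable template-matching observer:

1. **Optotypes** — the 10 Sloan letters (C D H K N O R S V Z), rendered from
   geometric primitives on the canonical 5×5 grid (stroke = height/5) at
   255×255 px, 92 dpi, 2-m viewing (0.4746 arcmin/px), for sizes −0.5 … +1.3
   logMAR in 0.1 steps (a letter at *L* logMAR subtends 5·10^*L* arcmin).
2. **Optics** — a generalized pupil over a 5-mm aperture with
   population-average higher-order aberrations plus induced defocus
   (Z₂⁰ = *D*·R²/4√3 µm) gives an OTF on the image frequency grid by pupil
   autocorrelation; test images are filtered with defocus, templates without.
3. **Neural stage** — both pass a radial low-pass neural transfer function;
   zero-mean Gaussian noise of variance 0.144 is added to the test image.
4. **Decision** — the noisy test image is matched against all 10 same-size
   templates by sliding normalized cross-correlation restricted to the
   letter region; peaks ≥ 0.95 are candidates, the highest peak answers,
   three-decimal ties are broken at random, and with no candidate the
   observer still answers (forced choice).
5. **Psychophysics** — a method-of-constant-stimuli session (11 sizes × 10
   presentations) produces a psychometric function fitted with a cumulative
   Gaussian by maximum likelihood; acuity is the size at 51.9% correct and
   the fitted σ measures precision.

A fluctuating trial samples the defocus sinusoid every 1 ms over a 300-ms
epoch placed at a uniformly random phase, and one of five temporal decision
strategies — **average** (all 300 ms), **least** (best of six 50-ms bins),
**early**/**late** (first/last 100 ms), or **mixed** — selects which samples
are averaged into the effective retinal image. By linearity of the optics,
averaging defocused images equals filtering once with the averaged OTF,
which is how the engine computes it.

The package also provides the zero-crossing analysis that explains the
frequency dependence: a uniformly placed window of duration *d* on a
zero-mean sinusoid contains a zero-defocus instant with probability
min(1, 2 *f* *d*) — certain at 2 Hz for a 300-ms epoch (zeros every 250 ms),
but only 30% / 15% at 0.5 / 0.25 Hz.

## Worked example

```python
import numpy as np
from acuitysim import AcuityEngine, DefocusSignal, StudyConfig, run_condition
from acuitysim.psychophysics import regression_by_frequency

engine = AcuityEngine()                       # bank + optics + neural stage
cfg = StudyConfig(master_seed=1, n_replicates=10, mc_reps=0)

baseline = run_condition(engine, DefocusSignal(0.0, 1.0), "average", cfg)
print(f"baseline acuity {baseline.acuity:+.3f} +/- {baseline.acuity_sem:.3f} logMAR")

acuity = {}
for a in (0.25, 0.5, 1.0, 2.0):               # least strategy, 2-Hz fluctuation
    r = run_condition(engine, DefocusSignal(a, 2.0), "least", cfg)
    acuity[a] = r.acuity
    print(f"A={a:4} D: {r.acuity:+.3f} logMAR")
print(regression_by_frequency(acuity))
```

prints (seed 1):

```
baseline acuity -0.044 +/- 0.014 logMAR
A=0.25 D: -0.019 logMAR
A= 0.5 D: -0.021 logMAR
A= 1.0 D: +0.084 logMAR
A= 2.0 D: +0.128 logMAR
{'slope': 0.0906..., 'intercept': -0.0418..., 'r2': 0.8827...}
```

Read: with the least-defocus strategy a 2-Hz fluctuation costs only
~0.09 logMAR per diopter of amplitude, because every 300-ms epoch contains a
zero-defocus moment the observer can exploit; at 0.25 Hz the same sweep
yields ~0.33 logMAR/D.

The same experiments are scriptable from the shell:

```bash
acuitysim bank build --out bank/                    # PNGs + manifest
acuitysim run grid --seed 1 --out results/          # full 17x5 study grid
acuitysim run static --seed 1 --out results-static/
acuitysim run offset --seed 1 --out results-offset/ # 0.5 D about 0.5-D hyperopia
acuitysim report table1 --results results/results.csv
acuitysim zero-crossing --frequency 0.5 --duration 0.3
```

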