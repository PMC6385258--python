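# qdc3dm

Calibrated single-molecule counting of quantum-dot-labeled growth factors
in 3D fluorescence microscopy, together with the ligand–receptor binding
simulator that predicts how many molecules a cell population should bind.

Quantum dots (QDs) blink: a single emitter switches stochastically between
a bright and a dark state, so its intensity trace has exactly two levels,
a spot with two QDs has three, and so on. `qdc3dm` exploits this to count
molecules absolutely, with no reliance on absolute brightness standards:

1. **Single-QD identification** — for each diffraction-limited spot, the
   100-bin histogram of its 3×3-pixel intensity trace
   I<sub>spot</sub><sup>2D</sup>(t) is fit to a Gaussian background plus a
   skewed-Gaussian signal; spots whose traces show clean two-level
   dynamics are single QDs.
2. **Single-QD intensity calibration** — the deconvolved 3D intensities
   I<sub>spot</sub><sup>3DD</sup> (3×3×11-voxel integrals after
   Richardson–Lucy deconvolution) of those spots are averaged into
   ⟨I<sub>1QD</sub><sup>3DD</sup>⟩.
3. **Spot calibration** — every spot's QD number is
   N<sub>QD,spot</sub> = I<sub>spot</sub><sup>3DD</sup> /
   ⟨I<sub>1QD</sub><sup>3DD</sup>⟩, and a cell's total is
   N<sub>QD,cell</sub> = Σ N<sub>QD,spot</sub>.

The number of QD components per trace is chosen by minimum AIC,
AIC = n<sub>bin</sub> ln(RSS/n<sub>bin</sub>) + 2(3 n<sub>Gauss</sub> − 1),
over mixtures of 2–5 components that pass four quality criteria
(fit correlation ≥ 0.98, every component ≥ 8% of area, pairwise overlap
≤ 75%, component area within 20% of its data region).

Downstream analyses include membrane-surface reconstruction by 3D alpha
shape (α = 50), per-spot relative radial distance ρ from the nucleus with
internalization at ρ ≤ 0.8, and an EGF–EGFR binding simulator: per-cell
receptor numbers N<sub>R</sub> ~ Gamma(a = 3.34, mean 10⁵), pseudo-first-
order kinetics dB/dt = k<sub>on</sub>[EGF]₀(N<sub>R</sub> − B − C) −
(k<sub>off</sub> + k<sub>int</sub>)B, dC/dt = k<sub>int</sub>B, and
Poisson intrinsic noise around each cell's kinetic mean.

A seeded synthetic microscope (`qdc3dm.synthscope`) renders blinking
emitters under a separable 3D Gaussian PSF with shot and read noise, so
every stage is testable against ground truth.

## Worked example

Predict the per-cell bound-EGF distribution for a 5-minute 0.1 nM QD-EGF
pulse on ice (QD:EGF = 3:1, so 0.03 nM EGF):

```python
from qdc3dm import kinetics

params = kinetics.KineticParams.from_preset("4C", egf0=0.03e-9, t=300.0)
receptors = kinetics.ReceptorDistribution(a=3.34, mean_nr=1e5)
pop = kinetics.population_distribution(params, receptors)
print(f"mean {pop.mean:.2f} EGF/cell, CV {100 * pop.cv:.1f}%")
```

prints

```
mean 8.89 EGF/cell, CV 64.2%
```

i.e. a cell with average receptor expression binds ~9 ligands in 5 minutes
at this concentration, and receptor heterogeneity plus Poisson binding
noise spread the population to a coefficient of variation of ~64% — most
of the cell-to-cell variability at low dose is biological, not technical.

Counting molecules in a synthetic field end to end:

```python
import numpy as np
from qdc3dm import deconv, pipeline, synthscope

optics = synthscope.OpticsConfig()
scene = synthscope.make_spot_field(30, (96, 96), n_planes=40,
                                   n_qd=np.r_[[1]*20, [2]*6, [3]*4], seed=11)
rng = np.random.default_rng(53)
movie = synthscope.render_timeseries(scene, optics, 600, seed=rng)
for em in scene.emitters:
    em.states = None          # fresh blinking during the z-scan
stack = synthscope.render_stack3d(scene, optics, 40, seed=rng)
psf = deconv.gaussian_psf(optics.psf_sigma_xy_px, optics.psf_sigma_z_planes)

result = pipeline.run_arrays(movie, stack, psf, seed=1)
print(f"{result.calibration.n_single} single QDs -> "
      f"calibration {result.calibration.mean_i_1qd_3dd:.0f} counts")
print(f"N_QD,cell = {result.cell.n_qd_cell:.1f}  (truth: 44)")
```

prints

```
16 single QDs -> calibration 2725 counts
N_QD,cell = 43.9  (truth: 44)
```

The same pipeline is scriptable from the shell via the `qdc3dm` command
(`simulate`, `detect`, `blink`, `deconv`, `count`, `internalize`,
`simulate-binding`, `run`).

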