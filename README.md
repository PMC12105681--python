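# clusterpdf

Solution-state structure analysis of small metal nanoclusters from X-ray
total scattering, built for DNA-stabilized silver clusters of the
Ag16Cl2-core type: two DNA decamers and two chloride caps around sixteen
silver atoms arranged in four axial channels.

Crystallography answers "what is the structure in the crystal"; this
package asks how much that structure changes once the cluster is dissolved.
The observable is the reduced pair distribution function (PDF)

    G(r) = (s / r) * sum_{i<j} 2 w_ij N(r; r_ij, sigma_ij),

the sine Fourier transform of the background-subtracted total-scattering
signal F(Q), modelled as a sum of Gaussians over all atom pairs with
X-ray weights `w_ij = Z_i Z_j / <Z>^2` and widths
`sigma_ij^2 = (B_iso,i + B_iso,j) / 8 pi^2 + sigma_0^2`. The pipeline:

1. **Reduction** — scaled subtraction of the aqueous-DNA background in Q
   space and the transform `G(r) = (2/pi) \int F(Q) sin(Qr) dQ`.
2. **Two-stage refinement** — bounded trust-region least squares on every
   atomic coordinate plus a scale (55 parameters for 18 atoms), then an
   empirical solvation wave `A sin(2 pi r / lambda + phi) exp(-r/xi)` that
   absorbs the solvent-restructuring signal around a dissolved ion.
3. **Perturbation-ensemble refinement** — hundreds of refinements from
   randomly perturbed starts (±0.2 Å per coordinate) map the distribution
   of structures consistent with the data, because a single 18-atom PDF
   under-determines 55 parameters.
4. **Distortion geometry** — per-atom displacement vectors between the
   crystal reference and the refined ensemble average, and signed rotation
   angles about the cluster's principal (PCA) axis, grouped by Ag channel
   and DNA strand.
5. **DNA conformation** — a Biso broadening scan that asks how much
   isotropic displacement smearing the crystal-DNA PDF needs to match the
   solution DNA signal; the optimum converts to an RMS atomic displacement
   via `u = sqrt(B_iso / 8 pi^2)`.

A synthetic-data module generates toy clusters with known channel-twist
distortion fields, solvation waves, noise, and DNA-like backgrounds, so the
entire pipeline is testable end to end without any experimental download.

## Worked example

```python
import numpy as np
import clusterpdf as cp

# ground truth: toy 16 Ag + 2 Cl cluster, channels twisted by known angles
reference, channels = cp.make_toy_cluster()
distorted, truth = cp.apply_distortion(
    reference, channels, cp.DistortionSpec((9.0, 12.0, -3.0, -3.0), jitter=0.05, seed=0)
)

# observable: PDF + solvation wave + 1% noise
r = cp.default_rgrid(16.0, 0.01)
gmax = np.abs(cp.calc_pdf(distorted, r).g).max()
wave = cp.SolvationWave(0.1 * gmax, 7.0, 0.8, 6.0)
data = cp.simulate_pdf(distorted, wave, 0.01 * gmax, r, seed=1)

# 50-model perturbation ensemble from the undistorted reference
opts = cp.RefinementOptions(max_iter=150, tol=1e-8, rigid_groups=channels)
ens = cp.run_ensemble(reference, data,
                      cp.EnsembleSpec(n_models=50, max_disp=0.2, base_seed=100), opts)
print({k: round(v, 3) for k, v in ens.rw_summary().items()})

avg = cp.average_structure(ens)
stats = cp.channel_stats(cp.analyze_distortion(reference, avg, channel_map=channels))
for ch in ("ch1", "ch2", "ch3", "ch4"):
    print(ch, round(stats[ch]["mean_angle_deg"], 2), stats[ch]["sense"])
```

prints (seed 0 workflow):

```
{'min': 0.093, 'max': 0.174, 'mean': 0.12}
ch1 3.81 counterclockwise
ch2 7.83 counterclockwise
ch3 -7.51 clockwise
ch4 -4.47 clockwise
```

The fit quality Rw ≈ 0.09–0.17 across the ensemble; the recovered channel
rotations reproduce the two-counterclockwise / two-clockwise pattern of the
generating field. Note that a rigid rotation of the whole cluster about its
axis leaves every pair distance unchanged, so the PDF determines the twist
pattern only up to a common additive constant — the recovered angles are the
zero-net-rotation representative of the true field (9, 12, −3, −3) minus its
mean 3.75°.

The same workflow runs from the shell:

```bash
clusterpdf run --seed 0 --outdir out          # simulate -> ... -> dna-compare
clusterpdf ensemble --config my_config.yaml --n-models 100
```

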