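# cki — 3D creatine-kinase imaging with ³¹P magnetization-transfer MR fingerprinting

Creatine kinase (CK) buffers cellular energy by catalysing the
phosphate exchange PCr + ADP ⇌ Cr + ATP. Its pseudo-first-order forward
rate constant k<sub>CK</sub> (s⁻¹) is a marker of brain bioenergetics, but
mapping it in vivo requires combining ³¹P magnetization-transfer
spectroscopy with fast volumetric encoding. This package implements the
complete desk-scale counterpart of such an acquisition-and-analysis chain:

- **Sequence** — a bSSFP-type train of 800 frequency-selective excitations
  (four sinusoidal flip-angle blocks, A·sin(π/200·x)<sup>0.6</sup>, A = 35°
  for the PCr blocks and 25° for the γATP blocks, RF phase alternating
  0°/180°, TR = 19.82 ms with a 4 ms echo-shift Te⁺ on every second PCr
  excitation), each block prepared by a 40 ms asymmetric inversion pulse.
- **Spin model** — a two-pool (optionally three-pool, with inorganic
  phosphate) Bloch-McConnell simulator with chemical exchange on all
  magnetization components, propagated by matrix exponentials; detailed
  balance ties the reverse rate to the forward one, k_rev = k_CK · Cr with
  Cr = M0(PCr)/M0(ATP).
- **Dictionary matching** — fingerprint atoms are 1200-point conditioned,
  unit-norm vectors ([Re PCr ∥ Im PCr ∥ Re ATP] after per-half phasing);
  (k_CK, Cr, T1PCr, ΔB0) are estimated by exhaustive maximum inner
  product.
- **Reconstruction** — Voronoi density compensation with a radial
  half-period Hann window, Kaiser-Bessel convolution gridding of the
  861-point spiral (33 % k-space coverage), whitened-SVD coil combination
  with noise covariance from interleaved average differences, and
  Marchenko-Pastur PCA denoising.
- **Phantom** — a digital brain (32 × 32 × 11, 7.2 × 7.2 × 20 mm³ voxels)
  with gray/white-matter parameter values, smooth coil sensitivities and a
  seeded exact-DFT forward model to raw multi-coil spiral k-space.
- **Analysis** — SNR and coefficient-of-variation metrics, split-half
  reproducibility, ROI tables, and functional CKI: percent-change k_CK
  maps between rest and stimulation with activation clusters (change ≥
  10 %, size ≥ 20).

## Worked example

```python
import numpy as np
from cki import sequence, dictionary, phantom, recon, analysis

sched = sequence.build_schedule()          # 800 excitations, 4 prep pulses
grid = dictionary.ParameterGrid(
    k_ck=np.round(np.arange(0.20, 0.401, 0.01), 4),
    cr=np.round(np.arange(1.0, 1.501, 0.05), 4),
    t1_pcr=np.round(np.arange(3.75, 5.251, 0.25), 4),
    delta_b0=np.arange(-6.0, 6.01, 2.0),
)
dic = dictionary.generate_dictionary(grid, sched)

ph = phantom.make_phantom(seed=2,
        geometry=phantom.PhantomGeometry(b0_amplitude_hz=5, b0_frontal_hz=4))
coil = phantom.make_coil_model(n_coils=4, shape=ph.shape)
traj = recon.design_spiral()               # 861 points, 33% coverage
raw = phantom.forward_simulate(ph, sched, coil, traj,
                               n_averages=4, noise_sigma=10.0, seed=3)
series = recon.reconstruct(raw)
maps = analysis.match_maps(series, dic, sched, mask=ph.brain_mask)

gm = ph.labels == phantom.GRAY
print(f"GM k_CK  {maps.k_ck[gm].mean():.3f} ± {maps.k_ck[gm].std():.3f}  1/s")
print(f"GM Cr    {maps.cr[gm].mean():.3f} ± {maps.cr[gm].std():.3f}")
print(f"GM T1PCr {maps.t1_pcr[gm].mean():.2f} ± {maps.t1_pcr[gm].std():.2f}  s")
```

prints (noise realisation of seed 3):

```
GM k_CK  0.308 ± 0.015  1/s
GM Cr    1.270 ± 0.040
GM T1PCr 4.65 ± 0.14  s
```

i.e. the matched gray-matter maps recover the phantom's generating values
(k_CK 0.30 s⁻¹, Cr 1.27, T1PCr 4.67 s) with a few-percent voxelwise
scatter from noise and grid quantization.

A command-line interface mirrors the library:
`cki dict build`, `cki recon`, `cki match`, `cki fcki`, `cki robustness`.

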