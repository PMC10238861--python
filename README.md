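# cortexflow

Tools for asking how cortical actomyosin flows sort membrane-associated
proteins — built around the *C. elegans* zygote, where anterior-directed
cortical flow during polarity establishment segregates PAR proteins into
anterior and posterior membrane domains.

The package covers the full computational workflow:

- **`particle_sim`** — stochastic simulation of membrane particles
  (lateral diffusion + advection + exponential membrane turnover at
  constant particle number) and rendering of synthetic two-channel
  near-TIRF movies (PSF-blurred spots; a flow-warped speckle "cortex"
  channel) for benchmarking every downstream stage against ground truth.
- **`spot_tracking`** — Crocker–Grier-style subpixel spot detection and
  frame-to-frame linking into trajectories.
- **`flow_field`** — two-pass FFT cross-correlation PIV on the cortex
  channel, outlier filtering, and bicubic flow-vector lookup.
- **`advection_stats`** — the core estimator: particle displacements are
  projected parallel/perpendicular to the local flow vector; the Gaussian
  displacement distributions give the advection velocity υₓ = ⟨Δx⟩/τ and
  the **cortex coupling coefficient** cc = υₓ/ν̄ (1 = fully entrained,
  0 = oblivious to the flow), plus step-size diffusivity estimates,
  binned analyses and detection-power calculations.
- **`pde_polarity`** — a 1D advection–diffusion–membrane-exchange model

      ∂A/∂t = D ∂²A/∂x² + ∂(vA)/∂x + k_on·A_cyt − k_off·A,
      A_cyt = ρ_A − ψ·Ā,

  on a 60 µm membrane with an experimentally fitted flow profile v(x)
  active for 500 s, predicting segregation efficiency (asymmetry index
  ASI, posterior depletion) and its post-flow decay as a function of
  membrane diffusivity D and off-rate k_off, including a two-state
  (fast/slow exchanging) extension.
- **`membrane_quant`** — membrane concentration profiles from
  straightened-membrane images (Gaussian + error-function cross-section
  fits), image-side ASI/depletion/M:C metrics, and FRAP recovery fits
  I(t) = I₀ + P·(1 − e^(−t/τ)) giving the turnover time τ = 1/k_off.
- **`pipeline` / CLI** — one-command orchestration with deterministic
  seeding and provenance reports.

## Worked example

Solve the polarity model at the parameters measured for PAR-2
(D ≈ 0.1 µm²/s, k_off ≈ 0.005 s⁻¹):

```sh
cortexflow pde -D 0.1 --koff 0.005 --tflow 500 --tpost 1500 --out metrics.json
```

prints

```json
{
 "peak_asi": 0.2558699288261882,
 "peak_depletion": 0.634790889416884,
 "t_half_asi_s": 108.49754134309221,
 "t_half_depletion_s": 128.41532624742406
}
```

i.e. 500 s of cortical flow is predicted to enrich such a molecule
anteriorly to a modest asymmetry index of ~0.26 (on a scale where 0.5
means a fully cleared posterior), deplete the posterior pole by ~63%
relative to the membrane mean, and lose half of that asymmetry within
~110 s once flows cease — segregation is real but transient unless
membrane binding is stabilised further.

The same reference point from Python, plus a synthetic tracking
benchmark:

```python
import cortexflow as cf

sol = cf.solve_pde(cf.PdeParams(D=0.1, k_off=0.005))
m = cf.compute_metrics(sol)
print(m.peak_asi, m.peak_depletion, m.t_half_asi)

# simulate fully entrained particles and recover cc = 1
cfg = cf.SimulationConfig(n_particles=1000, D=0.05, v_parallel=0.1,
                          duration=0.5, frame_interval=0.1, seed=0)
traj, truth = cf.simulate_trajectories(cfg)
flow = cf.FlowField.uniform(0.1, 0.0, extent=(300, 300), spacing=50)
est = cf.fit_advection(cf.project_displacements(traj, flow, tau_frames=5))
print(est.cc)  # ~1.0 within sampling error
```

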