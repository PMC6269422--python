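# ccakit

Comprehensive correlation analysis for fast hexagonal detector-array
fluctuation data.

Modern confocal systems project the point spread function onto a small
hexagonal array of ~32 analog detectors that can be read out at
microsecond rates.  A single spot acquisition on such a "nanocamera"
contains, at once, the information that several classical fluorescence
fluctuation techniques extract separately.  `ccakit` turns one
`T x 32` intensity record (plus one excitation-off dark record) into:

* **Corrected FCS + N&B** — multi-tau correlation with an analog-detector
  correction: `G1(tau) = (<dI dI> - <dI0 dI0>) / (<I> - <I0>)^2`, where
  the dark terms come from the dark record.  Offset, dark variance and
  detector cross-talk cancel; the gain cancels identically in `G`.
  Single-component diffusion fits give `tau_D`, `G0`, the mean molecule
  number `<N> = gamma/G1(0)` and the apparent brightness
  `B_analog = <I1> G1(0) / t_sample`.
* **Spot-variation FCS** — summing nested detector subsets synthesizes
  four observation volumes (effective waists 144-196 nm) from one
  acquisition.  The intercepts of `tau_D(w^2)` and of `N(V_eff)`,
  `V_eff = pi^(3/2) w^3 A`, place the measurement on the *intercept
  plot*: microdomain (+y) vs meshwork (-y), exclusion (+x) vs
  aggregation (-x), free at the origin.
* **2D pair correlation** — cross-correlation from the central element
  to the elements at the four hexagonal radii (50-132 nm) reads out
  diffusion anisotropy and, against a free-diffusion reference,
  a per-direction connectivity map.
* **iMSD** — the amplitude decay of ring-2 spatiotemporal correlations,
  `G(0,0,tau) = gamma/(N pi sigma^2(tau))`, inverted to
  `sigma^2_theta(tau) = C <G(0)>_Ring / G_theta(0,tau)` along the three
  hexagonal axes; linear for free diffusion (`sigma^2 = sigma^2(0) +
  4 D tau`), saturating at `sigma^2(0) + L_conf^2/3` for confinement.

A physics-faithful simulator (Brownian emitters, per-element Gaussian
detection volumes, Poisson photons, analog gain/offset/dark-noise model,
structured environments: microdomains, meshworks, barriers, excluded
volumes, corrals) provides ground truth for every stage, so the entire
stack is testable without a microscope.  `docs/methods.md` documents the
models, conventions and known limitations.

## Worked example

Simulate 0.6 s of free diffusion (D = 30 um^2/s, 100 molecules in a
1 x 1 x 2 um box, 2.46 us sampling, analog detector with gain 750,
offset 200, dark noise sigma 20) and run the full analysis:

```python
import ccakit as ck

cfg  = ck.SimulationConfig(n_steps=250_000, seed=1)
analog, photons = ck.simulate_trace(cfg)          # T x 32 analog + clean trace
dark = ck.simulate_dark_trace(cfg, n_steps=250_000)

report = ck.run_full_cca(analog, dark)
fcs1 = report.fcs["1"]
print(f"level 1: w = {fcs1['w_nm']:.0f} nm, tau_D = {fcs1['tau_D_s']*1e6:.0f} us, "
      f"N = {fcs1['N']:.2f}, D = {fcs1['D_um2_s']:.1f} um^2/s")
print("quadrant:", report.spotvar["quadrant"])
print("iMSD model:", report.imsd["model"],
      f"D = {report.imsd['D_free_um2_s']:.1f} um^2/s")
```

prints (seed 1):

```
level 1: w = 144 nm, tau_D = 177 us, N = 0.83, D = 29.3 um^2/s
quadrant: free/unstructured
iMSD model: free D = 30.1 um^2/s
```

`tau_D = w^2/(4D)` at the 144 nm center-element waist is 173 us, the
analytic occupancy of the largest virtual pinhole is
`gamma * c * V_eff = 1.92` molecules (level-1: 0.87), and the input D is
30 um^2/s — the fitted values land within the few-percent scatter
expected at this trace length, and a free run classifies at the origin
of the intercept plot with a linear iMSD.

The same pipeline is scriptable from the shell:

```sh
ccakit --seed 1 --out-dir out simulate --n-steps 250000
ccakit --out-dir out dark --n-steps 250000
ccakit --out-dir out report out/trace.ome.tif --dark out/dark.ome.tif
```

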