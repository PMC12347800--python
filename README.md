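# membranekit

Desk-scale analysis of passive solute permeation through lipid bilayers.

Molecular-dynamics studies of membrane permeation all lean on the same
small analysis layer: density profiles along the membrane normal z,
membrane structural parameters, membrane/water partition coefficients,
and free-energy (PMF) profiles obtained either by inverse-Boltzmann
inversion of a solute density or by adaptive-bias sampling.
`membranekit` implements that layer as a tested, reusable package, and
pairs it with a synthetic bilayer generator whose ground truth is known
exactly — so every estimator can be validated end-to-end without running
an MD engine.

It is aimed at membrane biophysicists and simulation practitioners who
want the analysis machinery (or a reference implementation to test their
own against), not at replacing trajectory engines.

## What it computes

**Structural parameters** (per-frame, with block-averaged uncertainties):

- Area per lipid, APL = 2 L_x L_y / n_lipid.
- Bilayer thickness D_HH: peak-to-peak distance of the two headgroup
  maxima of the electron density profile, with quadratic sub-bin peak
  refinement.
- Volume per lipid, VPL = D_HH · APL / 2.
- Deuterium order parameter per tail carbon,
  S_CD = ½⟨3 cos²Θ − 1⟩, Θ the angle between a C–H bond and the
  bilayer normal.

**Partitioning.** The membrane/bulk partition coefficient compares mean
solute densities inside and outside the membrane slab |z| ≤ D_HH/2:

    P_memb/bulk = [∫_{-D_HH/2}^{+D_HH/2} ρ dz / D_HH]
                / [(∫_{-Z/2}^{+Z/2} ρ dz − ∫_{-D_HH/2}^{+D_HH/2} ρ dz) / (Z_box − D_HH)]

computed by trapezoidal integration with explicit interpolated cut
points, so the result is robust to the histogram bin width.

**PMFs.** Inverse-Boltzmann inversion PMF(z) = −RT ln ρ(z)/ρ₀ with the
aqueous bulk density ρ₀ as reference; zero-count bins are masked, never
pseudo-counted.  Profiles can be symmetrized, averaged over replicas
with per-bin standard deviations, decomposed into the four-region
membrane model (interfacial water / headgroups / acyl chains / bilayer
center), and reduced to features: central and headgroup-band barriers,
minima with positions and depths, and barrier widths at half height.

**Toy AWH sampler.** A one-particle reimplementation of the
accelerated-weight-histogram adaptive-bias scheme on 1-D analytic
potentials: overdamped Langevin dynamics plus a stiff harmonic coupling
(default 12,800 kJ mol⁻¹ nm⁻²) to a grid reaction coordinate that is
Gibbs-resampled under the current bias, with the standard two-stage
(covering-doubled, then 1/n) weight-histogram update.  It validates the
free-energy layer end-to-end against analytic potentials.

**Synthetic systems.** `build_bilayer_system` generates an idealized
hydrated bilayer (default: 128 lipids per leaflet, 50 waters per lipid,
150 mM salt, 100 solute molecules) with controllable area per lipid,
thickness, headgroup scatter, tail order and a solute distribution drawn
from any prescribed PMF — the ground truth every estimator is tested
against.

## Worked example

```python
import numpy as np
from membranekit import (BilayerSpec, build_bilayer_system, compute_density_profile,
    area_per_lipid, membrane_thickness, volume_per_lipid, deuterium_order_parameter,
    estimate_bulk_density, partition_coefficient, pmf_from_density, symmetrize_pmf,
    extract_features)

def solute_pmf(z):  # minima -3 kJ/mol at |z|=1.2 nm, central barrier +4
    az = np.abs(np.asarray(z, float))
    out = np.zeros_like(az)
    rim = (az > 1.2) & (az < 2.0)
    out[rim] = -1.5 * (1.0 + np.cos(np.pi * (az[rim] - 1.2) / 0.8))
    core = az <= 1.2
    out[core] = -3.0 + 3.5 * (1.0 + np.cos(np.pi * az[core] / 1.2))
    return out

spec = BilayerSpec(n_per_leaflet=64, n_frames=10, n_solute=400,
                   solute_pmf=solute_pmf, seed=0)
ens = build_bilayer_system(spec)

apl = area_per_lipid(ens, spec.n_lipid)
eprof = compute_density_profile(ens, "all", "electron", bin_width=0.05)
dhh = membrane_thickness(eprof)
scd = deuterium_order_parameter(ens)
print(f"APL  = {apl.value:.3f} +/- {apl.sd:.3f} nm^2")
print(f"D_HH = {dhh.value:.3f} +/- {dhh.sd:.3f} nm")
print(f"VPL  = {volume_per_lipid(dhh.value, apl.value):.3f} nm^3")
print(f"S_CD (chain mean) = {scd['scd'].mean():.3f}")

sol = compute_density_profile(ens, "solute", "number", bin_width=0.1)
part = partition_coefficient(sol, dhh.value)
print(f"P_memb/bulk = {part.p_memb_bulk:.2f}  logP = {part.logp:.2f}")

z_bulk = dhh.value / 2 + 0.5
rho0 = estimate_bulk_density(sol, z_bulk).value
pmf = symmetrize_pmf(pmf_from_density(sol, rho0, spec.temperature, bulk_z=z_bulk))
feats = extract_features(pmf, dhh.value, smoothing_window=5)
print(f"central barrier vs bulk = {feats.central_barrier_vs_bulk:.2f} kJ/mol")
print(f"deepest minimum = {min(m[1] for m in feats.minima):.2f} kJ/mol")
```

Output:

```
APL  = 0.618 +/- 0.000 nm^2
D_HH = 3.734 +/- 0.024 nm
VPL  = 1.154 nm^3
S_CD (chain mean) = -0.203
P_memb/bulk = 1.42  logP = 0.15
central barrier vs bulk = 4.58 kJ/mol
deepest minimum = -2.73 kJ/mol
```

The builder sets the lateral box from the APL target, so APL is
recovered exactly with zero spread (the box is constant across frames);
D_HH (target 3.732 nm) and the chain-averaged S_CD (target −0.2) come
back within their statistical errors.  The solute was drawn from a PMF
with a +4 kJ/mol central barrier and −3 kJ/mol interfacial minima; with
only 4,000 solute observations the inverse-Boltzmann features carry
roughly ±0.5–1 kJ/mol of counting noise, which is what the deviations
above show.  The positive logP says the solute is membrane-enriched,
consistent with its interfacial minima.

A `membranekit` command-line interface mirrors the library
(`build-synthetic`, `density`, `structure`, `partition`, `pmf`,
`features`, `awh-toy`, `run-all`); `run-all` chains the full pipeline
from a YAML config and writes CSV/JSON artifacts plus a manifest.

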