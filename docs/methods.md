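# Methods

This note records the models, conventions and numerical choices behind
`membranekit`, and what the synthetic validation does and does not
demonstrate about real trajectories.

## Units and geometry

Lengths in nm, energies in kJ/mol, masses in amu, temperatures in K,
times in ps; R = 8.314462618×10⁻³ kJ/(mol·K).  The bilayer midplane is
z = 0 with the upper leaflet at z > 0; boxes are orthorhombic and
coordinates are stored wrapped to [0, L) per axis.  All file I/O
(GRO/PDB/XTC/DCD via MDAnalysis, CSV/JSON/YAML for results and
configuration) converts units at the boundary.

## Synthetic bilayer generator

`build_bilayer_system` emulates a hydrated single-lipid-species bilayer
patch at the composition used throughout the package's validation:
128 lipids per leaflet, 50 waters per lipid headgroup, 150 mM NaCl,
100 solute molecules, at 330 K (345 K selectable for PE/PA-like
conditions).  Each lipid is a heavy headgroup bead (240 amu, 130 e⁻)
plus a chain of tail carbons carrying two explicit hydrogens each;
water, ions and solutes are single beads.  Geometry is imposed, not
simulated:

- The lateral box satisfies L_x L_y = n_per_leaflet · APL_target, so
  the area-per-lipid estimator recovers its target exactly (a box
  identity, constant across frames).
- Headgroup beads scatter normally (σ default 0.15 nm) around
  z = ±D_HH/2, so the electron-density headgroup peaks sit at the
  target thickness.  The tail-carbon ladder starts 3σ below the
  headgroup shell and the water slab starts 3σ above it: without this
  separation the neighboring density edges bias the peak position of
  the *total* electron profile by more than a histogram bin, i.e. the
  generator would not deliver the ground truth it claims.
- C–H orientations are drawn from a two-component axial mixture
  (isotropic + delta at Θ = 90° for negative targets, + delta at
  Θ = 0° for positive ones) whose ½⟨3cos²Θ−1⟩ moment equals the S_CD
  target exactly.
- The aqueous slab thickness follows from the water count at liquid
  number density (33 nm⁻³ near 330–345 K).  Ion counts are
  round(c_salt · V_slab · N_A) per species plus counterions for any
  declared headgroup charge; ions are placed uniformly (no Debye
  structure — they are bookkeeping here).
- Solute z positions are exact i.i.d. Boltzmann draws from a prescribed
  PMF via inverse-CDF on a ≤ 0.005 nm grid; frames are independent
  draws under a single seed (bit-reproducible).

The solute load of 100 molecules per 12,800 waters is reported as an
aqueous-phase molarity via the water mole ratio, 100/12,800 × 55.35 M =
0.432 M; a per-box-volume molarity is also available
(`box_molarity`) since the two conventions differ materially.

What the generator does **not** emulate: molecular connectivity beyond
the C–H ladder, excluded volume, electrostatics, undulations,
equilibration dynamics, or frame-to-frame correlation.  Passing the
round-trip tests therefore shows the estimators are correct and
unbiased on ideal geometry with realistic counting noise — it does not
show robustness to force-field artifacts or slow collective modes.

## Density profiles

Per-species densities along z are binned (default 0.02 nm, bin count
forced odd so one bin is centered on the midplane) after recentering
each frame on the mass-weighted center of all lipid particles, which
removes drift and matches the convention of measuring solute positions
relative to the bilayer center of mass.  Weighting is by mass, electron
count or particle number.  The two outermost bins absorb the sub-bin
residual L_z − n_bins·Δz, making the profile integral equal the exact
per-frame species weight (the conservation invariant tested to 10⁻⁹
relative).  Per-block profiles (default 5 equal trajectory blocks) ride
along for downstream uncertainty estimates.

Symmetrization, out(z) = (in(z)+in(−z))/2, is offered at the density
level for presentation; the canonical place to symmetrize is the PMF
level (below), because the log of an average differs from the average
of a log.

## Structural estimators

- **APL**: 2 L_x L_y / n_lipid per frame; uncertainty is the standard
  error of 5 block means (the method behind reported ± values is a
  package choice; block averaging is conventional for correlated MD
  data).
- **D_HH**: the highest local maximum of the electron-density profile
  on each side of the midplane, refined by a quadratic fit through the
  peak bin and its neighbors; ties between equal maxima break toward
  larger |z| because headgroup peaks are the outermost features.  A
  profile with no maximum on one side (e.g. a single central peak) is
  an error, not a guess.
- **VPL** = D_HH · APL / 2, with first-order error propagation when
  computed jointly.
- **S_CD**: per carbon index, averaged over both C–H bonds, all lipids
  and frames; leaflet-agnostic since cos² is sign-free.  Carbons with
  no bonded hydrogens are skipped with a warning.  Real-trajectory use
  assumes explicit hydrogens (no united-atom reconstruction).

## Partitioning and PMFs

The membrane/bulk partition coefficient uses composite trapezoidal
integration of the piecewise-linear profile with explicit interpolated
cut points at ±D_HH/2 and edge-value extension to ±Z_box/2, making P
bin-width-robust and exactly scale-invariant.  A profile with zero bulk
integral is an error (P is undefined, not infinite).  `logp_contrast`
reports the percent reduction in |logP| between two systems.

Inverse-Boltzmann PMFs mask zero-count bins rather than clamping them:
pseudo-counts would bias barrier heights, and no smoothing rule is
imposed on the data.  After inversion the profile is re-referenced so
the mean over the declared bulk region (|z| > D_HH/2 + margin, default
margin 0.5 nm) is exactly zero.  Replica combination takes the per-bin
mean and sample standard deviation over PMFs on identical grids, with
the valid mask intersected.

Feature extraction runs on a centered moving-average smoothed copy
(default window 5 bins; window 1 disables smoothing) and finds extrema
by sign changes of the discrete derivative, with flat stretches carried
through.  The central barrier (|z| < D_HH/4) is reported both vs bulk
and vs the mean of its flanking minima — published single numbers
rarely state their reference, so both are kept side by side.  When a
flank has no strict minimum (a plateau), the lowest value on that side
substitutes.  Widths are full widths at half the height above the
flanking minima, by linear interpolation.  The headgroup-band barrier
is sought in D_HH/4 < |z| < D_HH/2 + 0.5 nm.  Absent features are
`None`, never zero.

The four-region decomposition (perturbed interfacial water I,
headgroups II, acyl chains III, bilayer center IV) places II/I at the
outermost water–lipid density crossover, II/III at the inner edge where
headgroup density falls below 10% of its peak, III/IV at |z| = D_HH/4,
and extends region I by a 0.5 nm water-perturbation margin.

## Toy AWH sampler

A single particle obeys overdamped Langevin dynamics in U(x) plus a
harmonic coupling k/2 (x−λ)² to a grid point λ; λ is Gibbs-resampled
each step with weights ∝ exp[(f(λ) − k/2 (x−λ)²)/RT], where the bias f
is the current free-energy estimate (flat target).  Every
`update_interval` steps (default 10) the normalized λ weights are
accumulated and the estimate updated by
f_j ← f_j − RT[ln(Nρ_j + w_j) − ln((N+1)ρ_j)], magnitude ~RT/N.

Defaults follow the production-scale settings where they exist: force
constant 12,800 kJ mol⁻¹ nm⁻², diffusion estimate 2.5×10⁻⁴ nm²/ps,
initial error estimate 10 kJ/mol.  Package choices where they do not:
friction 200 ps⁻¹ (unit mass, so the particle diffusion is
D_x = RT/γ ≈ 0.014 nm²/ps; the Euler step is stable when
k·Δt/γ < 2), timestep 0.01 ps, grid of ≥ 10 uniform points, reflecting
walls half a grid spacing beyond the edge λ points (walls on the edge
points themselves halve the x-neighborhood of the edge bins and bias
their estimates by ~RT ln 2).

The initial reference histogram size is
N₀ = RT·τ_cross/(ε₀·Δt_sample), τ_cross = L²/(2D): one diffusive grid
crossing then accumulates free-energy structure of order ε₀ per bin.
The heuristic is informative only when the supplied diffusion estimate
matches the system's actual mobility; the toy's validation runs pass
its own D_x = RT/γ.  N is doubled at each covering (every grid point
visited since the last covering); the final stage begins at the first
covering where the doubled N overtakes the actual sample count, after
which N grows by one per sample (1/n decay).  The estimate is
deconvolved from the harmonic smoothing (variance RT/k) by the
first-order stiff-spring correction U ≈ F + (RT/2k)(F'²/RT − F''),
which is negligible at the default k.  Convergence is monitored as the
per-snapshot max deviation from the final estimate with a Mann–Kendall
(Kendall-τ vs time) trend statistic; because the series is
self-referenced, its late tail is not a meaningful error measure.

Validation problem sizes: flat and double-well landscapes use 2×10⁷
Langevin steps on 41–53-point grids (seconds of wall time), at which
the flat landscape flattens below 0.5 kJ/mol spread, a 10 kJ/mol
double-well barrier is recovered within a few tenths of kJ/mol, and
the production-half λ visit histogram is uniform within ~±15% per bin.
This is a didactic single-walker 1-D scheme — no multi-walker sharing,
no multidimensional coordinates, no coupling to molecular systems.

## Degenerate inputs and tie-breaks

Empty species selections, all-zero density profiles, missing headgroup
peaks, non-orthorhombic boxes, unmapped atoms on read, and aqueous
slabs too thin to contain a bulk region all raise errors naming the
condition.  Exact zero water–lipid crossovers on a grid point are taken
at that point.  S_CD targets outside [−0.5, 1.0], the mathematical
range of ½⟨3cos²Θ−1⟩, are rejected.

## Known limitations

- The synthetic lipids are geometric stand-ins; estimator validation
  does not certify behavior on disordered or phase-separated bilayers.
- D_HH assumes the headgroup peaks are the highest local maxima per
  side of the electron profile; exotic electron-dense solutes could
  violate this.
- The pipeline's leaflet assignment on read uses the first frame's
  headgroup positions relative to the box midplane and assumes a
  membrane that does not cross the periodic boundary after recentering.
- The AWH toy supports only the flat target distribution and a single
  walker.
- No permeability coefficients (no local diffusivity estimation) and
  no 2-D lateral density maps.
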