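"""Idealized hydrated-bilayer ensembles with known ground truth.

This module builds coarse, geometrically idealized stand-ins for hydrated
single-species phospholipid bilayers: each lipid is a headgroup bead plus a
chain of tail carbons carrying two explicit hydrogens each; water, ions and
solutes are single beads.  There is no force field, no energy minimization
and no realistic water geometry — the point is that every structural
observable (area per lipid, headgroup-peak thickness, tail order parameter,
solute distribution along the membrane normal) is imposed by construction,
so the estimators in :mod:`membranekit.membrane_structure`,
:mod:`membranekit.density_profiles` and
:mod:`membranekit.permeation_energetics` can be validated against exact
ground truth.

Geometry convention: z = 0 is the bilayer midplane, the upper leaflet has
z > 0, boxes are orthorhombic, and stored coordinates are wrapped to
[0, L) per axis (the midplane therefore sits at z = L_z/2 in stored
coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import AVOGADRO, WATER_NUMBER_DENSITY, rt

__all__ = [
    "BilayerSpec",
    "ParticleEnsemble",
    "SPECIES",
    "LIPID_SPECIES",
    "build_bilayer_system",
    "sample_solute_positions",
    "generate_orientation_sample",
    "aqueous_molarity",
    "box_molarity",
]

#: Recognized per-particle species tags.
SPECIES = (
    "lipid-head",
    "lipid-tail-carbon",
    "tail-hydrogen",
    "water",
    "ion",
    "solute",
)

#: Tags that together constitute "the lipid" for recentering purposes.
LIPID_SPECIES = ("lipid-head", "lipid-tail-carbon", "tail-hydrogen")

# Bead masses (amu) and electron counts for the idealized particles.
# The headgroup bead lumps phosphate + glycerol backbone + polar group;
# tail carbons/hydrogens are atomic; water, ions and solutes are beads.
_BEAD_PROPS = {
    "lipid-head": (240.0, 130.0),
    "lipid-tail-carbon": (12.011, 6.0),
    "tail-hydrogen": (1.008, 1.0),
    "water": (18.015, 10.0),
    "ion": (29.2, 14.0),  # mean of Na+ (10 e-) and Cl- (18 e-)
    "solute": (100.0, 54.0),
}

_CH_BOND_LENGTH = 0.109  # nm


@dataclass(frozen=True)
class BilayerSpec:
    """Recipe for an idealized bilayer + solute ensemble.

    Defaults describe a typical simulated hydrated single-lipid
    bilayer: 128 lipids per leaflet, 50 waters per lipid, 150 mM salt,
    100 solute molecules, simulated at 330 K; the structural targets
    default to DPPC-like values (APL 0.618 nm^2, D_HH 3.732 nm).
    """

    n_per_leaflet: int = 128
    hydration: int = 50  # waters per lipid
    apl_target: float = 0.618  # nm^2
    dhh_target: float = 3.732  # nm
    headgroup_sigma: float = 0.15  # nm, z-scatter of headgroup beads
    scd_target: float = -0.2  # dimensionless, in [-0.5, 1.0]
    tail_carbons: int = 15
    salt_conc: float = 0.15  # mol/L in the aqueous slabs
    n_solute: int = 100
    solute_pmf: Optional[Callable[[np.ndarray], np.ndarray]] = None
    headgroup_charge: int = 0  # e per lipid; negative lipids get counterions
    temperature: float = 330.0  # K
    n_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_leaflet < 1:
            raise ValueError("n_per_leaflet must be >= 1")
        if self.hydration < 0:
            raise ValueError("hydration must be >= 0")
        if self.apl_target <= 0:
            raise ValueError("apl_target must be positive")
        if self.dhh_target <= 0:
            raise ValueError("dhh_target must be positive")
        if not -0.5 <= self.scd_target <= 1.0:
            raise ValueError(
                f"scd_target must lie in [-0.5, 1.0], got {self.scd_target}"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.tail_carbons < 1:
            raise ValueError("tail_carbons must be >= 1")

    # -- derived counts ---------------------------------------------------
    @property
    def n_lipid(self) -> int:
        return 2 * self.n_per_leaflet

    @property
    def n_water(self) -> int:
        return self.hydration * self.n_lipid


@dataclass
class ParticleEnsemble:
    """Frames of particle coordinates plus immutable per-particle metadata.

    coords has shape (n_frames, n_particles, 3) in nm, wrapped into
    [0, L) per axis; box has shape (n_frames, 3).  Metadata arrays are
    shared across frames.  Tail hydrogens reference their parent carbon
    through ``parent_carbon`` (index into the particle arrays, -1 for
    non-hydrogens); ``carbon_index`` is the 0-based position along the
    acyl chain (-1 where not applicable).
    """

    coords: np.ndarray
    box: np.ndarray
    species: np.ndarray
    mass: np.ndarray
    electron_count: np.ndarray
    resid: np.ndarray
    leaflet: np.ndarray
    carbon_index: np.ndarray
    parent_carbon: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_particles, 3)")
        if self.box.shape != (self.coords.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        n = self.coords.shape[1]
        for name in ("species", "mass", "electron_count", "resid", "leaflet",
                     "carbon_index", "parent_carbon"):
            arr = np.asarray(getattr(self, name))
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        unknown = set(np.unique(self.species)) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species tags: {sorted(unknown)}")
        h = self.species == "tail-hydrogen"
        if np.any(self.parent_carbon[h] < 0):
            raise ValueError("every tail-hydrogen must reference a parent carbon")
        if h.any() and not np.all(
            self.species[self.parent_carbon[h]] == "lipid-tail-carbon"
        ):
            raise ValueError("tail-hydrogen parents must be tail carbons")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def wrap(self) -> None:
        """Wrap all coordinates into [0, L) per axis, in place."""
        for f in range(self.n_frames):
            self.coords[f] = np.mod(self.coords[f], self.box[f])

    def species_mask(self, tag: str) -> np.ndarray:
        """Boolean mask for a species tag or the aliases 'all', 'lipid',
        'headgroup'."""
        if tag == "all":
            return np.ones(self.n_particles, dtype=bool)
        if tag == "lipid":
            return np.isin(self.species, LIPID_SPECIES)
        if tag == "headgroup":
            return self.species == "lipid-head"
        if tag not in SPECIES:
            raise ValueError(f"unknown species tag {tag!r}")
        return self.species == tag

    def counts(self) -> dict:
        """Audit of molecule counts by species (hydrogens fold into lipids)."""
        return {
            "lipid": int(np.sum(self.species == "lipid-head")),
            "water": int(np.sum(self.species == "water")),
            "ion": int(np.sum(self.species == "ion")),
            "solute": int(np.sum(self.species == "solute")),
        }


# ---------------------------------------------------------------------------
# solute position sampling
# ---------------------------------------------------------------------------

def sample_solute_positions(
    pmf: Optional[Callable[[np.ndarray], np.ndarray]],
    z_range: tuple,
    n: int,
    temperature: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw i.i.d. z positions from the Boltzmann density exp(-pmf/RT).

    The density is normalized on ``z_range`` and inverted via the CDF on a
    fine grid (step <= 0.005 nm), so draws are exact up to linear
    interpolation of the CDF.  ``pmf`` may be None for a flat profile.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = float(z_range[0]), float(z_range[1])
    if not hi > lo:
        raise ValueError("z_range must be an increasing interval")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    npts = max(int(np.ceil((hi - lo) / 0.005)) + 1, 101)
    grid = np.linspace(lo, hi, npts)
    if pmf is None:
        u = np.asarray(np.zeros_like(grid))
    else:
        u = np.asarray(pmf(grid), dtype=float)
        if u.shape != grid.shape:
            raise ValueError("pmf must be vectorized over z")
        if not np.all(np.isfinite(u)):
            raise ValueError("pmf must be finite on the whole z_range")
    w = np.exp(-(u - u.min()) / rt(temperature))
    cdf = cumulative_trapezoid(w, grid, initial=0.0)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def generate_orientation_sample(
    scd_target: float, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Unit C-H vectors from an axially symmetric distribution with
    E[(3 cos^2 T - 1)/2] = scd_target.

    Construction: a two-component mixture of an isotropic orientation
    (order 0) with either the perpendicular delta T=90 deg (order -1/2,
    for negative targets, weight -2*scd_target) or the parallel delta
    T=0 (order +1, for positive targets, weight scd_target).  The mixture
    moment is exact, so the sample estimator converges to the target.
    """
    if not -0.5 <= scd_target <= 1.0:
        raise ValueError(f"scd_target must lie in [-0.5, 1.0], got {scd_target}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cos_t = rng.uniform(-1.0, 1.0, n)  # isotropic component
    if scd_target < 0:
        aligned = rng.random(n) < (-2.0 * scd_target)
        cos_t[aligned] = 0.0
    elif scd_target > 0:
        aligned = rng.random(n) < scd_target
        cos_t[aligned] = np.sign(rng.random(np.sum(aligned)) - 0.5)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    return np.column_stack(
        (sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t)
    )


# ---------------------------------------------------------------------------
# concentration bookkeeping
# ---------------------------------------------------------------------------

def aqueous_molarity(n_solute: int, n_water: int, water_molarity: float = 55.35) -> float:
    """Solute concentration as an aqueous-phase molarity (mol/L) via the
    water mole ratio: n_solute / n_water * [H2O]."""
    if n_water <= 0:
        raise ValueError("n_water must be positive")
    return n_solute / n_water * water_molarity


def box_molarity(n_solute: int, box_volume_nm3: float) -> float:
    """Solute concentration per total box volume (mol/L)."""
    if box_volume_nm3 <= 0:
        raise ValueError("box volume must be positive")
    return n_solute / (box_volume_nm3 * 1e-24 * AVOGADRO)


# ---------------------------------------------------------------------------
# the builder
# ---------------------------------------------------------------------------

def _lattice_xy(n: int, lx: float, ly: float) -> np.ndarray:
    """n lattice sites roughly uniform over the lateral box."""
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    xs = (np.arange(ncol) + 0.5) * lx / ncol
    ys = (np.arange(nrow) + 0.5) * ly / nrow
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack((xx.ravel()[:n], yy.ravel()[:n]))


def build_bilayer_system(spec: BilayerSpec) -> ParticleEnsemble:
    """Build the idealized bilayer ensemble described by ``spec``.

    The lateral box is fixed by the area-per-lipid target
    (L_x * L_y = n_per_leaflet * apl_target), headgroup beads scatter
    around z = +/- dhh_target/2, tail carbons descend toward the midplane
    and each carries two hydrogens whose C-H orientations are drawn so
    the deuterium-order-parameter estimator has expectation scd_target.
    Waters, ions and solutes populate the two aqueous slabs; solute z
    positions follow the Boltzmann density of ``spec.solute_pmf``.
    Frames are independent draws; the box is constant across frames.
    """
    rng = np.random.default_rng(spec.seed)

    area = spec.n_per_leaflet * spec.apl_target
    lx = ly = float(np.sqrt(area))
    half_dhh = spec.dhh_target / 2.0

    # aqueous slab thickness from the water count at liquid density; a
    # 3-sigma gap between headgroup shell and water keeps the electron
    # density peak at +/- dhh/2 unbiased by the water edge
    slab = spec.n_water / (2.0 * WATER_NUMBER_DENSITY * area) if spec.n_water else 1.0
    if slab < 2.0 * spec.headgroup_sigma:
        raise ValueError(
            "no bulk region: aqueous slab thinner than 2*headgroup_sigma "
            f"({slab:.3f} nm < {2 * spec.headgroup_sigma:.3f} nm)"
        )
    gap = 3.0 * spec.headgroup_sigma
    lz = spec.dhh_target + 2.0 * (gap + slab)
    box = np.array([lx, ly, lz])

    # aqueous-slab volume (both slabs) sets the salt ion count
    v_slab_nm3 = 2.0 * slab * area
    n_salt = int(round(spec.salt_conc * v_slab_nm3 * 1e-24 * AVOGADRO))
    n_counter = spec.n_lipid * abs(spec.headgroup_charge)
    n_ion = 2 * n_salt + n_counter

    c = spec.tail_carbons
    z_top = half_dhh - 3.0 * spec.headgroup_sigma  # chain top, clear of the head peak
    if z_top <= 0:
        raise ValueError("headgroup_sigma too large relative to dhh_target")
    per_lipid = 1 + 3 * c  # head + carbons + 2 H per carbon
    n_lipid_particles = spec.n_lipid * per_lipid
    n_total = n_lipid_particles + spec.n_water + n_ion + spec.n_solute

    species = np.empty(n_total, dtype=object)
    mass = np.empty(n_total)
    electrons = np.empty(n_total)
    resid = np.zeros(n_total, dtype=int)
    leaflet = np.full(n_total, "none", dtype=object)
    carbon_index = np.full(n_total, -1, dtype=int)
    parent = np.full(n_total, -1, dtype=int)

    # ---- metadata layout (identical across frames) ----
    idx = 0
    res = 0
    lipid_slices = []
    for il in range(spec.n_lipid):
        side = "upper" if il < spec.n_per_leaflet else "lower"
        lo = idx
        species[idx] = "lipid-head"
        resid[idx] = res
        leaflet[idx] = side
        idx += 1
        for ic in range(c):
            species[idx] = "lipid-tail-carbon"
            resid[idx] = res
            leaflet[idx] = side
            carbon_index[idx] = ic
            c_at = idx
            idx += 1
            for _ in range(2):
                species[idx] = "tail-hydrogen"
                resid[idx] = res
                leaflet[idx] = side
                carbon_index[idx] = ic
                parent[idx] = c_at
                idx += 1
        lipid_slices.append((lo, idx))
        res += 1
    for _ in range(spec.n_water):
        species[idx] = "water"
        resid[idx] = res
        idx += 1
        res += 1
    for _ in range(n_ion):
        species[idx] = "ion"
        resid[idx] = res
        idx += 1
        res += 1
    for _ in range(spec.n_solute):
        species[idx] = "solute"
        resid[idx] = res
        idx += 1
        res += 1
    assert idx == n_total
    for tag, (m, e) in _BEAD_PROPS.items():
        sel = species == tag
        mass[sel] = m
        electrons[sel] = e

    # ---- per-frame coordinates ----
    sites = _lattice_xy(spec.n_per_leaflet, lx, ly)
    dz_c = z_top / c  # carbon layer spacing toward the midplane
    coords = np.empty((spec.n_frames, n_total, 3))
    for fr in range(spec.n_frames):
        pos = np.empty((n_total, 3))
        for il in range(spec.n_lipid):
            sgn = 1.0 if il < spec.n_per_leaflet else -1.0
            site = sites[il % spec.n_per_leaflet]
            lo, hi = lipid_slices[il]
            xy = site + rng.normal(0.0, 0.03, 2)
            j = lo
            pos[j, 0:2] = xy
            pos[j, 2] = sgn * (half_dhh + rng.normal(0.0, spec.headgroup_sigma))
            j += 1
            n_ch = 2 * c
            u = generate_orientation_sample(spec.scd_target, n_ch, rng)
            for ic in range(c):
                cz = sgn * (z_top - ic * dz_c + dz_c / 2.0)
                cxy = xy + rng.normal(0.0, 0.02, 2)
                pos[j, 0:2] = cxy
                pos[j, 2] = cz + rng.normal(0.0, 0.02)
                cpos = pos[j]
                j += 1
                for ih in range(2):
                    pos[j] = cpos + _CH_BOND_LENGTH * u[2 * ic + ih]
                    j += 1
        base = n_lipid_particles
        # waters and ions uniform in the two aqueous slabs
        n_aq = spec.n_water + n_ion
        if n_aq:
            zsgn = np.where(rng.random(n_aq) < 0.5, 1.0, -1.0)
            zaq = zsgn * rng.uniform(half_dhh + gap, lz / 2.0, n_aq)
            pos[base : base + n_aq, 0] = rng.uniform(0.0, lx, n_aq)
            pos[base : base + n_aq, 1] = rng.uniform(0.0, ly, n_aq)
            pos[base : base + n_aq, 2] = zaq
        base += n_aq
        if spec.n_solute:
            zs = sample_solute_positions(
                spec.solute_pmf,
                (-lz / 2.0, lz / 2.0),
                spec.n_solute,
                spec.temperature,
                rng,
            )
            pos[base:, 0] = rng.uniform(0.0, lx, spec.n_solute)
            pos[base:, 1] = rng.uniform(0.0, ly, spec.n_solute)
            pos[base:, 2] = zs
        # shift midplane to L_z/2 and wrap into [0, L)
        pos[:, 2] += lz / 2.0
        coords[fr] = np.mod(pos, box)

    ens = ParticleEnsemble(
        coords=coords,
        box=np.tile(box, (spec.n_frames, 1)),
        species=species,
        mass=mass,
        electron_count=electrons,
        resid=resid,
        leaflet=leaflet,
        carbon_index=carbon_index,
        parent_carbon=parent,
    )
    return ens
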