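"""Per-species density profiles along the membrane normal.

Profiles are binned on a uniform z grid that is symmetric about the
bilayer midplane (odd bin count, one bin centered on z = 0), after
recentering each frame on the center of mass of all lipid-tagged
particles.  Weighting is by mass (amu/nm^3), electron count (e-/nm^3) or
particle number (nm^-3).  The two outermost bins absorb the sub-bin
residual L_z - n_bins*bin_width so that the integral of the profile over
the box exactly equals the per-frame total weight of the species.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .synthetic_system import ParticleEnsemble

__all__ = [
    "DensityProfile",
    "compute_density_profile",
    "symmetrize_profile",
    "estimate_bulk_density",
    "BulkDensity",
]

WEIGHTINGS = ("mass", "electron", "number")


@dataclass
class DensityProfile:
    """Binned density of one species along z.

    z_centers is a uniform grid symmetric about 0; values are densities in
    amu/nm^3, e-/nm^3 or nm^-3 depending on ``weighting``.  ``block_values``
    (optional, shape n_blocks x n_bins) holds per-block profiles for
    uncertainty estimates downstream.
    """

    z_centers: np.ndarray
    values: np.ndarray
    bin_width: float
    weighting: str
    species: str
    n_frames: int
    box_area: float  # mean L_x * L_y, nm^2
    z_box: float  # mean L_z, nm
    block_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z_centers.shape != self.values.shape:
            raise ValueError("z_centers and values must have matching shapes")
        dz = np.diff(self.z_centers)
        if dz.size and np.max(np.abs(dz - self.bin_width)) >= 1e-9:
            raise ValueError("grid must be uniform with spacing bin_width")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        if np.any(self.values < 0):
            raise ValueError("densities must be nonnegative")

    @property
    def is_symmetric_grid(self) -> bool:
        return bool(np.allclose(self.z_centers, -self.z_centers[::-1], atol=1e-12))

    def integral(self) -> float:
        """Sum of values * bin_width (line density integral, per nm^2 of area)."""
        return float(np.sum(self.values) * self.bin_width)

    def total_weight(self) -> float:
        """Per-frame total species weight implied by the profile."""
        return self.integral() * self.box_area

    # ---- CSV round trip ----
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "z_nm": self.z_centers,
                "value": self.values,
                "weighting": self.weighting,
                "species": self.species,
                "bin_width": self.bin_width,
                "n_frames": self.n_frames,
            }
        )
        df.attrs["box_area"] = self.box_area
        header = f"# box_area={self.box_area!r} z_box={self.z_box!r}\n"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DensityProfile":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#"):
                for tok in first[1:].split():
                    k, _, v = tok.partition("=")
                    meta[k] = float(v)
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        return cls(
            z_centers=df["z_nm"].to_numpy(),
            values=df["value"].to_numpy(),
            bin_width=float(df["bin_width"].iloc[0]),
            weighting=str(df["weighting"].iloc[0]),
            species=str(df["species"].iloc[0]),
            n_frames=int(df["n_frames"].iloc[0]),
            box_area=meta.get("box_area", np.nan),
            z_box=meta.get("z_box", np.nan),
        )


def _weights(ensemble: ParticleEnsemble, mask: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "mass":
        return ensemble.mass[mask]
    if weighting == "electron":
        return ensemble.electron_count[mask]
    if weighting == "number":
        return np.ones(int(mask.sum()))
    raise ValueError(f"weighting must be one of {WEIGHTINGS}")


def compute_density_profile(
    ensemble: ParticleEnsemble,
    species: str,
    weighting: str = "mass",
    bin_width: float = 0.02,
    recenter: bool = True,
    n_blocks: int = 5,
) -> DensityProfile:
    """Bin the density of ``species`` along z, averaged over frames.

    Each frame is recentered so the lipid center of mass sits at z = 0
    before binning (ensembles with no lipid particles are binned about
    the box center instead).  The bin count floor(L_z / bin_width) is
    forced odd so one bin is centered on the midplane.
    """
    if ensemble.n_frames < 1:
        raise ValueError("ensemble has no frames")
    lz = float(np.mean(ensemble.box[:, 2]))
    if bin_width <= 0 or bin_width > lz / 8.0:
        raise ValueError("bin_width must be positive and <= L_z/8")
    mask = ensemble.species_mask(species)
    if not mask.any():
        raise ValueError(f"empty selection: no particles with species {species!r}")

    nbins = int(np.floor(lz / bin_width))
    if nbins % 2 == 0:
        nbins -= 1
    span = nbins * bin_width
    centers = (np.arange(nbins) - (nbins - 1) / 2.0) * bin_width

    lipid = ensemble.species_mask("lipid")
    lipid_any = bool(lipid.any())
    w = _weights(ensemble, mask, weighting)
    lw = ensemble.mass[lipid]

    per_frame = np.empty((ensemble.n_frames, nbins))
    areas = np.empty(ensemble.n_frames)
    for fr in range(ensemble.n_frames):
        bz = ensemble.box[fr, 2]
        area = ensemble.box[fr, 0] * ensemble.box[fr, 1]
        areas[fr] = area
        z = ensemble.coords[fr, :, 2]
        if recenter and lipid_any:
            z0 = float(np.average(z[lipid], weights=lw))
        else:
            z0 = bz / 2.0
        zc = np.mod(z - z0 + bz / 2.0, bz) - bz / 2.0
        idx = np.floor((zc + span / 2.0) / bin_width).astype(int)
        np.clip(idx, 0, nbins - 1, out=idx)  # edge bins absorb the residual
        hist = np.bincount(idx[mask], weights=w, minlength=nbins)
        per_frame[fr] = hist / (bin_width * area)

    values = per_frame.mean(axis=0)
    nb = min(n_blocks, ensemble.n_frames)
    blocks = np.array(
        [b.mean(axis=0) for b in np.array_split(per_frame, nb)]
    )
    return DensityProfile(
        z_centers=centers,
        values=values,
        bin_width=bin_width,
        weighting=weighting,
        species=species,
        n_frames=ensemble.n_frames,
        box_area=float(areas.mean()),
        z_box=lz,
        block_values=blocks,
    )


def symmetrize_profile(profile: DensityProfile) -> DensityProfile:
    """Average the profile with its mirror image: out(z) = (in(z)+in(-z))/2.

    Idempotent and integral-conserving; requires a grid symmetric about 0.
    """
    if not profile.is_symmetric_grid:
        raise ValueError("profile grid is not symmetric about z = 0")
    values = 0.5 * (profile.values + profile.values[::-1])
    blocks = None
    if profile.block_values is not None:
        blocks = 0.5 * (profile.block_values + profile.block_values[:, ::-1])
    return replace(profile, values=values, block_values=blocks)


class BulkDensity(NamedTuple):
    value: float
    n_bins: int


def estimate_bulk_density(profile: DensityProfile, z_bulk: float) -> BulkDensity:
    """Mean profile value over bins with |z_center| > z_bulk.

    ``z_bulk`` is typically D_HH/2 plus a safety margin.  Raises if fewer
    than 3 bins contribute.
    """
    sel = np.abs(profile.z_centers) > z_bulk
    n = int(sel.sum())
    if n < 3:
        raise ValueError(
            f"no bulk region: only {n} bins beyond |z| = {z_bulk:.3f} nm"
        )
    return BulkDensity(float(profile.values[sel].mean()), n)
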