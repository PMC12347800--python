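"""Permeation energetics: partitioning, inverse-Boltzmann PMFs and features.

The membrane/bulk partition coefficient compares the mean solute density
inside the membrane slab |z| <= D_HH/2 with the mean density of the
remaining (bulk) region:

    P_memb/bulk = [ I_memb / D_HH ] / [ (I_total - I_memb) / (Z_box - D_HH) ]

with I the trapezoidal integrals of the density profile and explicit
linear interpolation at the +/- D_HH/2 cut points, so the result is
robust to the bin width.

PMFs come from inverse-Boltzmann inversion of a density profile,
PMF(z) = -RT ln(rho(z)/rho0), with zero-count bins masked invalid (never
pseudo-counted).  Profiles can be symmetrized (the canonical place to
symmetrize is the PMF level), averaged over replicas, decomposed into the
four-region membrane model (interfacial water / headgroups / acyl chains
/ bilayer center), and reduced to barrier/minimum features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import rt
from .density_profiles import DensityProfile

__all__ = [
    "PartitionResult",
    "PMFProfile",
    "PMFFeatures",
    "RegionBoundaries",
    "partition_coefficient",
    "logp_contrast",
    "pmf_from_density",
    "symmetrize_pmf",
    "combine_replicas",
    "extract_features",
    "assign_regions",
]


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionResult:
    p_memb_bulk: float
    logp: float
    dhh_used: float
    z_box: float
    membrane_integral: float
    bulk_integral: float


def _trapz_with_cuts(z: np.ndarray, v: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal integral of the piecewise-linear profile on [a, b],
    with interpolated values at the cut points.  Outside the grid the
    profile is extended with its edge value."""
    if b <= a:
        return 0.0
    inner = (z > a) & (z < b)
    zz = np.concatenate(([a], z[inner], [b]))
    vv = np.concatenate(([np.interp(a, z, v)], v[inner], [np.interp(b, z, v)]))
    return float(np.trapezoid(vv, zz))


def partition_coefficient(profile: DensityProfile, dhh: float) -> PartitionResult:
    """Membrane/bulk partition coefficient of a solute density profile."""
    z_box = profile.z_box
    if not 0 < dhh < z_box:
        raise ValueError("dhh must satisfy 0 < dhh < z_box")
    z = profile.z_centers
    v = profile.values
    half = dhh / 2.0
    i_memb = _trapz_with_cuts(z, v, -half, half)
    i_total = _trapz_with_cuts(z, v, -z_box / 2.0, z_box / 2.0)
    i_bulk = i_total - i_memb
    if i_bulk <= 0.0:
        raise ValueError("no solute in bulk: partition coefficient undefined")
    if i_memb <= 0.0:
        raise ValueError("no solute in membrane slab: partition coefficient is zero")
    p = (i_memb / dhh) / (i_bulk / (z_box - dhh))
    return PartitionResult(
        p_memb_bulk=p,
        logp=float(np.log10(p)),
        dhh_used=dhh,
        z_box=z_box,
        membrane_integral=i_memb,
        bulk_integral=i_bulk,
    )


def logp_contrast(logp_a: float, logp_b: float) -> float:
    """Percent reduction in |logP| from system b to system a:
    100 * (|logp_b| - |logp_a|) / |logp_b|."""
    if logp_b == 0:
        raise ValueError("logp_b must be nonzero")
    return 100.0 * (abs(logp_b) - abs(logp_a)) / abs(logp_b)


# ---------------------------------------------------------------------------
# PMF profiles
# ---------------------------------------------------------------------------

@dataclass
class PMFProfile:
    """Free-energy profile along z, referenced so the bulk region is zero.

    ``mask`` marks valid bins; masked-out bins carry NaN.  ``one_sided``
    flags bins whose symmetrized value came from only one side.
    """

    z: np.ndarray
    values: np.ndarray
    temperature: float
    sd: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    reference: str = "bulk-zero"
    one_sided: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.one_sided is None:
            self.one_sided = np.zeros_like(self.mask)
        if self.z.shape != self.values.shape or self.z.shape != self.mask.shape:
            raise ValueError("z, values and mask must have matching shapes")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("valid bins must be finite")
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def is_symmetric_grid(self) -> bool:
        return bool(np.allclose(self.z, -self.z[::-1], atol=1e-12))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "z_nm": self.z,
                "pmf_kJmol": self.values,
                "sd_kJmol": self.sd if self.sd is not None else np.nan,
                "valid": self.mask.astype(int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, temperature: float) -> "PMFProfile":
        df = pd.read_csv(path)
        sd = df["sd_kJmol"].to_numpy()
        return cls(
            z=df["z_nm"].to_numpy(),
            values=df["pmf_kJmol"].to_numpy(),
            temperature=temperature,
            sd=None if np.all(np.isnan(sd)) else sd,
            mask=df["valid"].to_numpy().astype(bool),
        )


def pmf_from_density(
    profile: DensityProfile,
    rho0: float,
    temperature: float,
    bulk_z: Optional[float] = None,
) -> PMFProfile:
    """Inverse-Boltzmann PMF: -RT ln(rho(z)/rho0) on bins with rho > 0.

    Zero-count bins are masked invalid, never clamped.  If ``bulk_z`` is
    given, the profile is re-referenced so the mean over valid bins with
    |z| > bulk_z is exactly zero.
    """
    if rho0 <= 0:
        raise ValueError("rho0 must be positive")
    kt = rt(temperature)
    v = profile.values
    mask = v > 0
    if not mask.any():
        raise ValueError("all bins are empty; PMF undefined")
    with np.errstate(divide="ignore"):
        pmf = np.where(mask, -kt * np.log(v / rho0), np.nan)
    if bulk_z is not None:
        sel = mask & (np.abs(profile.z_centers) > bulk_z)
        if not sel.any():
            raise ValueError("no valid bins in the requested bulk region")
        pmf = pmf - np.nanmean(pmf[sel])
    return PMFProfile(z=profile.z_centers.copy(), values=pmf,
                      temperature=temperature, mask=mask)


def symmetrize_pmf(pmf: PMFProfile) -> PMFProfile:
    """out(z) = (in(z) + in(-z))/2 where both sides are valid; where only
    one side is valid that value is used and flagged one-sided."""
    if not pmf.is_symmetric_grid:
        raise ValueError("PMF grid is not symmetric about z = 0")
    v = pmf.values
    m = pmf.mask
    vr = v[::-1]
    mr = m[::-1]
    both = m & mr
    one = m ^ mr
    out = np.full_like(v, np.nan)
    out[both] = 0.5 * (v[both] + vr[both])
    out[one & m] = v[one & m]
    out[one & mr] = vr[one & mr]
    sd = None
    if pmf.sd is not None:
        sd = np.where(both, 0.5 * np.hypot(pmf.sd, pmf.sd[::-1]), np.nan)
        sd[one & m] = pmf.sd[one & m]
        sd[one & mr] = pmf.sd[::-1][one & mr]
    return PMFProfile(
        z=pmf.z.copy(),
        values=out,
        temperature=pmf.temperature,
        sd=sd,
        mask=m | mr,
        reference=pmf.reference,
        one_sided=one,
    )


def combine_replicas(pmfs: Sequence[PMFProfile]) -> PMFProfile:
    """Per-bin mean and sample sd over replica PMFs on identical grids;
    the valid mask is the intersection of the replicas' masks."""
    if len(pmfs) < 2:
        raise ValueError("need at least 2 replicas")
    z0 = pmfs[0].z
    for p in pmfs[1:]:
        if p.z.shape != z0.shape or not np.allclose(p.z, z0, atol=1e-12):
            raise ValueError("replica grids do not match")
    mask = np.logical_and.reduce([p.mask for p in pmfs])
    stack = np.vstack([p.values for p in pmfs])
    mean = np.where(mask, np.mean(stack, axis=0), np.nan)
    sd = np.where(mask, np.std(stack, axis=0, ddof=1), np.nan)
    return PMFProfile(
        z=z0.copy(),
        values=mean,
        temperature=pmfs[0].temperature,
        sd=sd,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PMFFeatures:
    """Barriers and minima of a PMF; fields are None when absent.

    Barrier values are relative to the bulk reference (0) unless the name
    says otherwise; minima are (position nm, depth kJ/mol vs bulk).
    """

    central_barrier_vs_bulk: Optional[float]
    central_barrier_vs_adjacent_min: Optional[float]
    central_barrier_position: Optional[float]
    central_barrier_width: Optional[float]
    outer_barrier: Optional[float]
    outer_barrier_position: Optional[float]
    minima: Tuple[Tuple[float, float], ...]

    def to_dict(self) -> dict:
        return {
            "central_barrier_vs_bulk": self.central_barrier_vs_bulk,
            "central_barrier_vs_adjacent_min": self.central_barrier_vs_adjacent_min,
            "central_barrier_position": self.central_barrier_position,
            "central_barrier_width": self.central_barrier_width,
            "outer_barrier": self.outer_barrier,
            "outer_barrier_position": self.outer_barrier_position,
            "minima": [list(m) for m in self.minima],
        }


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v.copy()
    return (
        pd.Series(v).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _extrema(v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima by derivative sign change."""
    d = np.diff(v)
    s = np.sign(d)
    # carry the sign through flat stretches
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    change = s[1:] * s[:-1]
    idx = np.where(change < 0)[0] + 1
    maxima = idx[s[idx - 1] > 0]
    minima = idx[s[idx - 1] < 0]
    return maxima, minima


def _half_height_width(
    z: np.ndarray, v: np.ndarray, peak: int, level: float
) -> Optional[float]:
    """Full width of the peak at ``level``, by linear interpolation of the
    crossings nearest to the peak on each side."""
    left = None
    for i in range(peak, 0, -1):
        if v[i - 1] <= level <= v[i] or v[i] <= level <= v[i - 1]:
            if v[i] != v[i - 1]:
                t = (level - v[i - 1]) / (v[i] - v[i - 1])
                left = z[i - 1] + t * (z[i] - z[i - 1])
            else:
                left = z[i - 1]
            break
    right = None
    for i in range(peak, v.size - 1):
        if v[i] <= level <= v[i + 1] or v[i + 1] <= level <= v[i]:
            if v[i + 1] != v[i]:
                t = (level - v[i]) / (v[i + 1] - v[i])
                right = z[i] + t * (z[i + 1] - z[i])
            else:
                right = z[i + 1]
            break
    if left is None or right is None or right <= left:
        return None
    return float(right - left)


def extract_features(
    pmf: PMFProfile, dhh: float, smoothing_window: int = 5
) -> PMFFeatures:
    """Locate the central barrier, the outer (headgroup-band) barrier and
    all minima of a PMF.

    Extrema are found on a centered-moving-average smoothed copy of the
    valid bins; the central barrier is the highest maximum with
    |z| < dhh/4, reported both vs bulk and vs the mean of its two
    flanking minima; the outer barrier is the highest maximum in the band
    dhh/4 < |z| < dhh/2 + 0.5 nm.  Width is the full width at half the
    height above the flanking minima.
    """
    m = pmf.mask
    if not m.any():
        raise ValueError("PMF has no valid bins")
    z = pmf.z[m]
    v = _moving_average(pmf.values[m], smoothing_window)
    maxima, minima = _extrema(v)

    min_list = tuple((float(z[i]), float(v[i])) for i in minima)

    central = None
    central_pos = None
    c_cand = maxima[np.abs(z[maxima]) < dhh / 4.0]
    if c_cand.size:
        j = c_cand[np.argmax(v[c_cand])]
        central = float(v[j])
        central_pos = float(z[j])

    vs_adj = None
    width = None
    if central is not None:
        left_min = minima[minima < j]
        right_min = minima[minima > j]
        flank = []
        # plateau-shaped flanks carry no strict sign change; fall back to
        # the lowest value on that side of the peak
        if left_min.size:
            flank.append(v[left_min[-1]])
        elif j > 0:
            flank.append(float(v[:j].min()))
        if right_min.size:
            flank.append(v[right_min[0]])
        elif j < v.size - 1:
            flank.append(float(v[j + 1:].min()))
        if flank:
            mean_flank = float(np.mean(flank))
            vs_adj = central - mean_flank
            level = central - 0.5 * (central - mean_flank)
            width = _half_height_width(z, v, j, level)

    outer = None
    outer_pos = None
    band = (np.abs(z[maxima]) > dhh / 4.0) & (
        np.abs(z[maxima]) < dhh / 2.0 + 0.5
    )
    o_cand = maxima[band]
    if o_cand.size:
        j2 = o_cand[np.argmax(v[o_cand])]
        outer = float(v[j2])
        outer_pos = float(z[j2])

    return PMFFeatures(
        central_barrier_vs_bulk=central,
        central_barrier_vs_adjacent_min=vs_adj,
        central_barrier_position=central_pos,
        central_barrier_width=width,
        outer_barrier=outer,
        outer_barrier_position=outer_pos,
        minima=min_list,
    )


# ---------------------------------------------------------------------------
# four-region membrane model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionBoundaries:
    """|z| intervals of the four-region membrane model, outermost (I,
    perturbed interfacial water) to center (IV, bilayer core)."""

    region_i: Tuple[float, float]
    region_ii: Tuple[float, float]
    region_iii: Tuple[float, float]
    region_iv: Tuple[float, float]

    def __post_init__(self) -> None:
        seq = [self.region_iv, self.region_iii, self.region_ii, self.region_i]
        for (a, b), (c, d) in zip(seq, seq[1:]):
            if not (a < b and abs(b - c) < 1e-9 and c < d):
                raise ValueError("regions must be contiguous, ordered IV -> I")

    def as_dict(self) -> dict:
        return {
            "I": list(self.region_i),
            "II": list(self.region_ii),
            "III": list(self.region_iii),
            "IV": list(self.region_iv),
        }

    def locate(self, z: float) -> Optional[str]:
        az = abs(z)
        for name, (a, b) in zip(
            ("IV", "III", "II", "I"),
            (self.region_iv, self.region_iii, self.region_ii, self.region_i),
        ):
            if a <= az < b:
                return name
        return None


def _fold(profile: DensityProfile) -> Tuple[np.ndarray, np.ndarray]:
    """Fold a symmetric-grid profile onto |z| >= 0 by averaging sides."""
    if not profile.is_symmetric_grid:
        raise ValueError("profile grid is not symmetric about z = 0")
    n = profile.z_centers.size
    half = n // 2
    z = profile.z_centers[half:]
    v = 0.5 * (profile.values[half:] + profile.values[: half + 1][::-1])
    return z, v


def assign_regions(
    lipid_profile: DensityProfile,
    water_profile: DensityProfile,
    headgroup_profile: DensityProfile,
    dhh: float,
    water_margin: float = 0.5,
) -> RegionBoundaries:
    """Four-region decomposition from lipid, water and headgroup profiles.

    Boundary II/I sits at the outermost water-lipid density crossover;
    II/III at the inner edge where headgroup density falls below 10% of
    its peak; III/IV at |z| = dhh/4.  Region I extends ``water_margin``
    beyond the II/I boundary.
    """
    z, lip = _fold(lipid_profile)
    zw, wat = _fold(water_profile)
    zh, head = _fold(headgroup_profile)
    if z.shape != zw.shape or z.shape != zh.shape or not np.allclose(z, zw):
        raise ValueError("profiles must share one grid")

    diff = wat - lip
    exact = np.where(diff == 0.0)[0]
    sign_change = np.where(diff[:-1] * diff[1:] < 0)[0]
    if sign_change.size == 0 and exact.size == 0:
        raise ValueError("bilayer not resolved: no water-lipid crossover")
    if exact.size and (sign_change.size == 0 or exact[-1] > sign_change[-1]):
        z_cross = float(z[exact[-1]])  # crossover exactly on a grid point
    else:
        i = sign_change[-1]  # outermost crossover
        t = diff[i] / (diff[i] - diff[i + 1])
        z_cross = float(z[i] + t * (z[i + 1] - z[i]))

    peak = int(np.argmax(head))
    if head[peak] <= 0:
        raise ValueError("bilayer not resolved: empty headgroup profile")
    thresh = 0.1 * head[peak]
    inner = None
    for i in range(peak, 0, -1):
        if head[i] >= thresh > head[i - 1]:
            t = (head[i] - thresh) / (head[i] - head[i - 1])
            inner = float(z[i] - t * (z[i] - z[i - 1]))
            break
    if inner is None:
        inner = float(z[0])

    z_iii_iv = dhh / 4.0
    inner = max(inner, z_iii_iv)  # keep ordering for very broad headgroups
    if not z_iii_iv < inner < z_cross:
        raise ValueError(
            "bilayer not resolved: region boundaries out of order "
            f"(dhh/4={z_iii_iv:.3f}, headgroup edge={inner:.3f}, "
            f"crossover={z_cross:.3f})"
        )
    return RegionBoundaries(
        region_i=(z_cross, z_cross + water_margin),
        region_ii=(inner, z_cross),
        region_iii=(z_iii_iv, inner),
        region_iv=(0.0, z_iii_iv),
    )
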