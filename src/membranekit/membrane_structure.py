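"""Membrane structural estimators: APL, D_HH, VPL and S_CD.

* APL (area per lipid): 2 L_x L_y / n_lipid, averaged over frames.
* D_HH (thickness): peak-to-peak distance of the two headgroup maxima of
  the electron density profile, with quadratic sub-bin refinement.
* VPL (volume per lipid): D_HH * APL / 2.
* S_CD (deuterium order parameter): (3<cos^2 T> - 1)/2 per tail carbon,
  with T the angle between a C-H bond and the bilayer normal.

Uncertainties are block-averaged: the trajectory is split into equal
blocks (default 5), the estimator is applied per block, and the reported
sd is the standard error of the block means.
"""

from __future__ import annotations

from typing import NamedTuple, Optional
import warnings

import numpy as np
import pandas as pd

from .density_profiles import DensityProfile
from .synthetic_system import ParticleEnsemble

__all__ = [
    "Measurement",
    "StructuralParams",
    "area_per_lipid",
    "membrane_thickness",
    "volume_per_lipid",
    "deuterium_order_parameter",
]


class Measurement(NamedTuple):
    value: float
    sd: float


class StructuralParams(NamedTuple):
    apl: Measurement
    dhh: Measurement
    vpl: Measurement
    scd: pd.DataFrame  # columns: carbon, scd, sd
    n_blocks: int


def _block_sd(block_vals: np.ndarray) -> float:
    block_vals = np.asarray(block_vals, dtype=float)
    if block_vals.size < 2:
        return 0.0
    return float(np.std(block_vals, ddof=1) / np.sqrt(block_vals.size))


def area_per_lipid(
    ensemble: ParticleEnsemble, n_lipid: int, n_blocks: int = 5
) -> Measurement:
    """Per-frame APL = 2 L_x L_y / n_lipid; mean and block-averaged sd."""
    if n_lipid < 2 or n_lipid % 2 != 0:
        raise ValueError("n_lipid must be even and >= 2 (two leaflets)")
    apl = 2.0 * ensemble.box[:, 0] * ensemble.box[:, 1] / n_lipid
    nb = min(n_blocks, len(apl))
    blocks = [b.mean() for b in np.array_split(apl, nb)]
    return Measurement(float(apl.mean()), _block_sd(np.array(blocks)))


def _locate_peak(z: np.ndarray, v: np.ndarray, bin_width: float) -> float:
    """Highest interior local maximum, quadratically refined.

    Ties between equal-height maxima are broken toward larger |z| (the
    headgroup peaks are the outermost features).
    """
    if v.size < 3:
        raise ValueError("no headgroup peaks: profile side too short")
    i = np.arange(1, v.size - 1)
    is_max = (v[i] > v[i - 1]) & (v[i] >= v[i + 1])
    cand = i[is_max]
    if cand.size == 0:
        raise ValueError("no headgroup peaks: no local maximum on one side")
    best = v[cand].max()
    cand = cand[np.isclose(v[cand], best, rtol=0.0, atol=0.0) | (v[cand] == best)]
    j = cand[np.argmax(np.abs(z[cand]))]
    denom = v[j - 1] - 2.0 * v[j] + v[j + 1]
    shift = 0.0 if denom == 0 else 0.5 * (v[j - 1] - v[j + 1]) / denom
    return float(z[j] + shift * bin_width)


def _thickness_of(z: np.ndarray, v: np.ndarray, bin_width: float) -> float:
    neg = z < 0
    pos = z > 0
    left = _locate_peak(z[neg], v[neg], bin_width)
    right = _locate_peak(z[pos], v[pos], bin_width)
    return right - left


def membrane_thickness(electron_profile: DensityProfile) -> Measurement:
    """D_HH from the two headgroup peaks of an electron density profile.

    The sd comes from per-block profiles when the profile carries them,
    else 0.
    """
    if electron_profile.weighting != "electron":
        raise ValueError("membrane_thickness requires an electron-weighted profile")
    z = electron_profile.z_centers
    v = electron_profile.values
    dhh = _thickness_of(z, v, electron_profile.bin_width)
    sd = 0.0
    if electron_profile.block_values is not None and len(electron_profile.block_values) > 1:
        vals = []
        for bv in electron_profile.block_values:
            try:
                vals.append(_thickness_of(z, bv, electron_profile.bin_width))
            except ValueError:
                continue
        if len(vals) > 1:
            sd = _block_sd(np.array(vals))
    return Measurement(dhh, sd)


def volume_per_lipid(dhh: float, apl: float) -> float:
    """VPL = D_HH * APL / 2 (nm^3)."""
    if dhh <= 0 or apl <= 0:
        raise ValueError("dhh and apl must both be positive")
    return dhh * apl / 2.0


def deuterium_order_parameter(
    ensemble: ParticleEnsemble, n_blocks: int = 5
) -> pd.DataFrame:
    """Per-carbon S_CD = (3<cos^2 T> - 1)/2 over all C-H bonds, lipids and
    frames; leaflet-agnostic since cos^2 is sign-free.

    Returns a DataFrame with columns ``carbon`` (0-based chain index),
    ``scd`` and block-averaged ``sd``.  Carbons without bonded hydrogens
    are skipped with a warning.
    """
    h = ensemble.species == "tail-hydrogen"
    if not h.any():
        raise ValueError("no tail hydrogens with parent-carbon links present")
    parents = ensemble.parent_carbon[h]
    cidx = ensemble.carbon_index[h]
    all_carbons = np.unique(
        ensemble.carbon_index[ensemble.species == "lipid-tail-carbon"]
    )
    missing = sorted(set(all_carbons.tolist()) - set(np.unique(cidx).tolist()))
    if missing:
        warnings.warn(f"carbons without bonded hydrogens skipped: {missing}")

    nb = min(n_blocks, ensemble.n_frames)
    frame_blocks = np.array_split(np.arange(ensemble.n_frames), nb)

    rows = []
    for carbon in np.unique(cidx):
        sel_h = h.copy()
        sel_h[h] = cidx == carbon
        hp = ensemble.parent_carbon[sel_h]
        block_means = []
        total_num = 0.0
        total_cnt = 0
        for frames in frame_blocks:
            vecs = (
                ensemble.coords[frames][:, sel_h, :]
                - ensemble.coords[frames][:, hp, :]
            )
            norm2 = np.sum(vecs * vecs, axis=-1)
            cos2 = vecs[..., 2] ** 2 / norm2
            s = 0.5 * (3.0 * cos2 - 1.0)
            block_means.append(float(s.mean()))
            total_num += float(s.sum())
            total_cnt += s.size
        rows.append(
            {
                "carbon": int(carbon),
                "scd": total_num / total_cnt,
                "sd": _block_sd(np.array(block_means)),
            }
        )
    return pd.DataFrame(rows)


def structural_params(
    ensemble: ParticleEnsemble,
    electron_profile: DensityProfile,
    n_lipid: Optional[int] = None,
    n_blocks: int = 5,
) -> StructuralParams:
    """All structural parameters at once; VPL derived jointly from the
    APL and D_HH estimates."""
    if n_lipid is None:
        n_lipid = int(np.sum(ensemble.species == "lipid-head"))
    apl = area_per_lipid(ensemble, n_lipid, n_blocks)
    dhh = membrane_thickness(electron_profile)
    vpl_val = volume_per_lipid(dhh.value, apl.value)
    # first-order error propagation for the product
    vpl_sd = 0.5 * np.hypot(dhh.value * apl.sd, apl.value * dhh.sd)
    scd = deuterium_order_parameter(ensemble, n_blocks)
    return StructuralParams(apl, dhh, Measurement(vpl_val, float(vpl_sd)), scd, n_blocks)
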