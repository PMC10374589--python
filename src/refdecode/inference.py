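"""Group-level inference on accuracy maps.

Participant accuracy maps are smoothed (6 mm FWHM Gaussian, mask-aware),
tested voxel-wise against chance (50%) with a one-sided one-sample t-test,
and corrected for family-wise error with a sign-flip cluster-based
permutation test: under the null the participant-level (accuracy - chance)
maps are sign-symmetric, so the null distribution of the maximum
suprathreshold cluster size is built by randomly flipping each participant's
map sign.  Clusters are formed at the t threshold corresponding to one-sided
p < 0.001 (df = n-1) using 26-connectivity, and a cluster is significant
when its FWE-corrected p -- the proportion of null maxima at least as large
-- falls below 0.05.  For n <= 12 participants all 2^n sign patterns are
enumerated (an exact test); otherwise random sign patterns are drawn with
the observed (identity) pattern included in the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def smooth_map(volume, mask, fwhm_mm: float = 6.0, voxel_size_mm=(3.0, 3.0, 3.0)):
    """Mask-aware Gaussian smoothing with the stated FWHM.

    Values outside the mask do not bleed in: the smoothed map is
    renormalized by the smoothed mask, so a constant map stays constant up
    to floating point even at mask edges.  ``fwhm_mm=0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    vol = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        out = np.where(mask, vol, np.nan)
        return out
    sigma = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in voxel_size_mm]
    filled = np.where(mask, vol, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    out = np.full(vol.shape, np.nan)
    inside = mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return out


def group_t_map(maps, chance: float = 50.0, mask=None):
    """Voxel-wise one-sample t of (accuracy - chance) across participants.

    Zero-variance voxels get t = 0 (logged).  Returns a 3D t-map with NaN
    outside the mask.
    """
    stack = np.asarray([np.asarray(m, dtype=float) for m in maps])
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if mask is None:
        mask = np.all(np.isfinite(stack), axis=0)
    d = stack[:, mask] - chance
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros(mean.shape)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    if np.any(~nz):
        logger.info("%d zero-variance voxels set to t=0", int(np.sum(~nz)))
    out = np.full(stack.shape[1:], np.nan)
    out[mask] = t
    return out


def _cluster_sizes(above: np.ndarray):
    labels, n = ndimage.label(above, structure=CONNECTIVITY_26)
    if n == 0:
        return labels, np.array([], dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, sizes


@dataclass
class GroupResult:
    t_map: np.ndarray
    cluster_table: pd.DataFrame  # label, n_voxels, volume_mm3, p_fwe, peak_ijk, peak_t
    significant_mask: np.ndarray
    n_permutations: int
    cluster_forming_t: float
    cluster_p: float
    fwe_p: float
    exhaustive: bool
    meta: dict = field(default_factory=dict)


def _sign_matrix(n: int, n_perm: int, rng) -> tuple:
    """(signs, exhaustive): sign patterns forming the permutation null."""
    if n <= 12:
        total = 2**n
        bits = (np.arange(total)[:, None] >> np.arange(n)[None, :]) & 1
        return 1 - 2 * bits.astype(float), True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0  # the observed labeling is part of the null
    return signs, False


def cluster_permutation_test(
    maps,
    chance: float = 50.0,
    cluster_p: float = 0.001,
    fwe_p: float = 0.05,
    n_perm: int = 5000,
    rng=None,
    mask=None,
    voxel_size_mm=(3.0, 3.0, 3.0),
) -> GroupResult:
    """Sign-flip cluster-based permutation test of accuracy > chance."""
    rng = np.random.default_rng(rng)
    stack = np.asarray([np.asarray(m, dtype=float) for m in maps])
    n = stack.shape[0]
    if mask is None:
        mask = np.all(np.isfinite(stack), axis=0)
    shape = stack.shape[1:]
    D = stack[:, mask] - chance  # n x V
    V = D.shape[1]
    t_crit = float(stats.t.ppf(1.0 - cluster_p, df=n - 1))

    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    P = signs.shape[0]
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if 1.0 / P > fwe_p:
        warnings.warn(
            f"{P} permutations cannot resolve p < {fwe_p}", stacklevel=2
        )

    # t statistics for all sign patterns at once: flipping signs leaves the
    # per-voxel sum of squares unchanged, so only the mean varies.
    ssq = np.sum(D**2, axis=0)  # V
    means = (signs @ D) / n  # P x V
    var = (ssq[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.where(var > 0, means / np.sqrt(var / n), 0.0)
    # zero variance with a nonzero mean is degenerate certainty, not a null
    tstats[(var == 0) & (means > 0)] = np.inf

    above = np.zeros(shape, dtype=bool)
    null_max = np.zeros(P)
    for p in range(P):
        above[mask] = tstats[p] > t_crit
        _, sizes = _cluster_sizes(above)
        null_max[p] = sizes.max() if len(sizes) else 0

    # observed statistics (identity sign pattern)
    sd_obs = np.std(D, axis=0, ddof=1)
    mean_obs = D.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs_flat = np.where(sd_obs > 0, mean_obs / (sd_obs / np.sqrt(n)), 0.0)
    t_obs_flat[(sd_obs == 0) & (mean_obs > 0)] = np.inf
    t_map = np.full(shape, np.nan)
    t_map[mask] = t_obs_flat
    above[mask] = t_obs_flat > t_crit
    labels, sizes = _cluster_sizes(above)

    rows = []
    sig_mask = np.zeros(shape, dtype=bool)
    vox_mm3 = float(np.prod(voxel_size_mm))
    for lab, size in enumerate(sizes, start=1):
        in_cluster = labels == lab
        pfwe = float(np.mean(null_max >= size))
        peak_flat = np.nanargmax(np.where(in_cluster, t_map, -np.inf))
        peak_ijk = np.unravel_index(peak_flat, shape)
        rows.append(
            {
                "label": lab,
                "n_voxels": int(size),
                "volume_mm3": float(size * vox_mm3),
                "p_fwe": pfwe,
                "peak_i": int(peak_ijk[0]),
                "peak_j": int(peak_ijk[1]),
                "peak_k": int(peak_ijk[2]),
                "peak_t": float(t_map[peak_ijk]),
            }
        )
        if pfwe < fwe_p:
            sig_mask |= in_cluster
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "n_voxels", "volume_mm3", "p_fwe",
            "peak_i", "peak_j", "peak_k", "peak_t",
        ],
    )
    return GroupResult(
        t_map=t_map,
        cluster_table=table,
        significant_mask=sig_mask,
        n_permutations=P,
        cluster_forming_t=t_crit,
        cluster_p=cluster_p,
        fwe_p=fwe_p,
        exhaustive=exhaustive,
        meta={"n_participants": n, "n_voxels": int(V), "cluster_labels": labels},
    )
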