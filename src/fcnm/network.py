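"""Core network mapping: seed FC maps, group statistics, overlap thresholding.

For each contrast seed, the per-subject map is the Fisher-z transformed
Pearson correlation between the seed's mean time series and every voxel in
the analysis (gray-matter) mask. Contrast-level maps are a voxel-wise
one-sample t-test across subjects, thresholded by Benjamini-Hochberg FDR
over the in-mask voxels, restricted to positive connectivity, and
binarized. The per-voxel fraction of contrasts whose binary map includes
the voxel forms the overlap probability map; voxels connected to at least
half of the contrast seeds (inclusive) define the network mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .volumes import BinaryMask, Volume3D, Volume4D

__all__ = [
    "FCMap",
    "GroupTMap",
    "NetworkProbabilityMap",
    "NetworkMask",
    "seed_timeseries",
    "fisher_z",
    "seed_fc_map",
    "group_onesample_t",
    "fdr_binarize",
    "overlap_probability",
    "threshold_network",
    "dice",
]

R_CLIP = 1.0 - 1e-7


@dataclass
class FCMap:
    z_map: Volume3D
    subject_id: str = ""
    contrast_id: str = ""
    zero_variance_mask: np.ndarray | None = None


@dataclass
class GroupTMap:
    t_map: Volume3D
    df: int
    p_map: Volume3D
    contrast_id: str = ""
    degenerate_mask: np.ndarray | None = None


@dataclass
class NetworkProbabilityMap:
    prob: Volume3D
    k_contrasts: int

    def __post_init__(self) -> None:
        scaled = self.prob.data * self.k_contrasts
        if not np.allclose(scaled, np.rint(scaled), atol=1e-9):
            raise ValueError("probability values times K must be integral")


@dataclass
class NetworkMask:
    mask: BinaryMask
    threshold: float = 0.5


def seed_timeseries(data: Volume4D, seed: BinaryMask) -> np.ndarray:
    """Unweighted mean time series across seed voxels."""
    if not seed.same_geometry(data):
        raise ValueError("seed geometry does not match data")
    sel = seed.data.astype(bool)
    if not sel.any():
        raise ValueError("empty seed")
    return data.data[sel].mean(axis=0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1: clip correlations before the z-transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def seed_fc_map(
    data: Volume4D,
    seed: BinaryMask,
    analysis_mask: BinaryMask,
    subject_id: str = "",
    contrast_id: str = "",
) -> FCMap:
    """Seed-to-voxel Pearson correlation map, Fisher-z transformed.

    Correlations are clipped to +-(1 - 1e-7) before atanh so the seed's own
    voxels stay finite; zero-variance voxels get z = 0 and are flagged.
    """
    if data.n_volumes < 3:
        raise ValueError("need T >= 3 for a correlation map")
    s = seed_timeseries(data, seed)
    s = s - s.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("seed time series has zero variance")
    sel = analysis_mask.data.astype(bool)
    Y = data.data[sel]  # V x T
    Y = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Y, axis=1)
    zero_var = norms == 0
    norms[zero_var] = 1.0
    r = (Y @ s) / (norms * s_norm)
    r[zero_var] = 0.0
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z_grid = np.zeros(data.shape[:3])
    z_grid[sel] = z
    zv_grid = np.zeros(data.shape[:3], dtype=bool)
    zv_grid[sel] = zero_var
    return FCMap(
        z_map=Volume3D(z_grid, data.affine, data.space_label),
        subject_id=subject_id,
        contrast_id=contrast_id,
        zero_variance_mask=zv_grid,
    )


def group_onesample_t(z_maps: Sequence[FCMap]) -> GroupTMap:
    """Voxel-wise one-sample t-test across subjects' z-maps.

    t = mean / (sd / sqrt(n)), df = n - 1, two-sided p. Voxels with zero
    across-subject variance get a signed infinite t sentinel with p = 0
    (p = 1 where the mean is also zero) and are flagged.
    """
    if len(z_maps) < 2:
        raise ValueError("need at least 2 subjects")
    ref = z_maps[0].z_map
    for m in z_maps[1:]:
        if not ref.same_geometry(m.z_map):
            raise ValueError("z-maps have inconsistent geometry")
    stack = np.stack([m.z_map.data for m in z_maps], axis=0)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate & (mean > 0)] = np.inf
    t[degenerate & (mean < 0)] = -np.inf
    t[degenerate & (mean == 0)] = 0.0
    df = n - 1
    p = np.where(
        degenerate, np.where(mean == 0, 1.0, 0.0), 2.0 * stats.t.sf(np.abs(t), df)
    )
    return GroupTMap(
        t_map=Volume3D(t, ref.affine, ref.space_label),
        df=df,
        p_map=Volume3D(p, ref.affine, ref.space_label),
        contrast_id=z_maps[0].contrast_id,
        degenerate_mask=degenerate,
    )


def fdr_binarize(
    tmap: GroupTMap,
    q: float = 0.05,
    positive_only: bool = True,
    analysis_mask: BinaryMask | None = None,
) -> BinaryMask:
    """Benjamini-Hochberg over in-mask voxel p-values, then binarize.

    The multiple-testing family is the set of in-mask voxels. With
    ``positive_only`` (default) only surviving voxels with t > 0 are set,
    restricting the map to positive connectivity.
    """
    vol = tmap.p_map
    if analysis_mask is not None:
        if not analysis_mask.same_geometry(vol):
            raise ValueError("analysis mask geometry mismatch")
        sel = analysis_mask.data.astype(bool)
    else:
        sel = np.ones(vol.shape, dtype=bool)
    if not sel.any():
        raise ValueError("empty analysis mask")
    p = vol.data[sel]
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    if positive_only:
        reject &= tmap.t_map.data[sel] > 0
    out = np.zeros(vol.shape, dtype=np.uint8)
    out[sel] = reject.astype(np.uint8)
    return BinaryMask(out, vol.affine, vol.space_label)


def overlap_probability(binary_maps: Sequence[BinaryMask]) -> NetworkProbabilityMap:
    """Per-voxel fraction of binary maps that include the voxel."""
    if len(binary_maps) < 1:
        raise ValueError("need at least one binary map")
    ref = binary_maps[0]
    for m in binary_maps[1:]:
        if not ref.same_geometry(m):
            raise ValueError("binary maps have inconsistent geometry")
    k = len(binary_maps)
    counts = np.sum([m.data for m in binary_maps], axis=0)
    return NetworkProbabilityMap(
        prob=Volume3D(counts / k, ref.affine, ref.space_label), k_contrasts=k
    )


def threshold_network(prob: NetworkProbabilityMap, tau: float = 0.5) -> NetworkMask:
    """Voxels connected to at least a fraction tau of contrast seeds (inclusive)."""
    if not (0 < tau <= 1):
        raise ValueError("tau must be in (0, 1]")
    mask = (prob.prob.data >= tau - 1e-12).astype(np.uint8)
    return NetworkMask(
        mask=BinaryMask(mask, prob.prob.affine, prob.prob.space_label), threshold=tau
    )


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    if not a.same_geometry(b):
        raise ValueError("masks have inconsistent geometry")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.sum((a.data > 0) & (b.data > 0)))
    return 2.0 * inter / (na + nb)
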