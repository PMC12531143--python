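"""Spatial association with receptor/transporter density maps.

A brain map (by default the unthresholded overlap-probability map restricted
to gray matter) and each receptor map are reduced to parcel means over a
shared parcellation; their spatial agreement is a Spearman (default) or
Pearson correlation; significance comes from a permutation null that
uniformly shuffles the receptor map's parcel assignment; and p-values are
Benjamini-Hochberg adjusted across the family of tracers tested.

The permutation p uses the add-one rule p = (b + 1) / (n_perm + 1), so it is
never exactly zero. The null is exchangeable, not spatial-autocorrelation
preserving; ``null="spin"`` is reserved as a hook for a spatially
constrained null and currently raises NotImplementedError.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasLabelMap
from .volumes import Volume3D

__all__ = [
    "ReceptorMap",
    "ParcelVector",
    "SpatialCorrelationResult",
    "parcellate",
    "spatial_correlation",
    "permutation_test",
    "fdr_across_maps",
    "neurochem_profile",
    "results_to_frame",
]


@dataclass
class ParcelVector:
    values: np.ndarray
    parcel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        if self.values.shape != self.parcel_ids.shape or self.values.ndim != 1:
            raise ValueError("values and parcel_ids must be matching 1-D arrays")
        if len(np.unique(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("parcel ids must be unique")


@dataclass
class ReceptorMap:
    tracer_label: str
    values: Volume3D | ParcelVector
    source_note: str = ""


@dataclass
class SpatialCorrelationResult:
    tracer_label: str
    r: float
    p_perm: float
    n_parcels: int
    method: str = "spearman"
    p_fdr: float | None = None
    significant: bool | None = None


def parcellate(volume: Volume3D, atlas: AtlasLabelMap) -> ParcelVector:
    """Mean in-parcel voxel value per parcel; empty parcels dropped with a warning."""
    if not volume.same_geometry(atlas.labels):
        raise ValueError("volume and parcel atlas must share geometry")
    ids, values = [], []
    empty = []
    for label in sorted(atlas.names):
        sel = atlas.labels.data == label
        if not sel.any():
            empty.append(label)
            continue
        ids.append(label)
        values.append(float(volume.data[sel].mean()))
    if not ids:
        raise ValueError("all parcels are empty")
    if empty:
        warnings.warn(f"dropped {len(empty)} empty parcels: {empty[:5]}...", stacklevel=2)
    return ParcelVector(np.array(values), np.array(ids))


def _aligned(x: ParcelVector, y: ParcelVector) -> tuple[np.ndarray, np.ndarray]:
    shared, ix, iy = np.intersect1d(x.parcel_ids, y.parcel_ids, return_indices=True)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared parcels")
    return x.values[ix], y.values[iy]


def spatial_correlation(x: ParcelVector, y: ParcelVector, method: str = "spearman") -> float:
    """Spearman (default) or Pearson correlation over shared parcels."""
    xv, yv = _aligned(x, y)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in a parcel vector")
    if method == "spearman":
        return float(stats.spearmanr(xv, yv).statistic)
    if method == "pearson":
        return float(stats.pearsonr(xv, yv).statistic)
    raise ValueError(f"unknown method {method!r}")


def permutation_test(
    x: ParcelVector,
    y: ParcelVector,
    n_perm: int = 5000,
    rng_seed: int | None = None,
    method: str = "spearman",
    null: str = "shuffle",
) -> tuple[float, float]:
    """Two-sided permutation p for the spatial correlation of x and y.

    Uniformly permutes y's parcel assignment; p = (#{|r*| >= |r_obs|} + 1)
    / (n_perm + 1). Returns (r_obs, p_perm); reproducible given rng_seed.
    """
    if null == "spin":
        raise NotImplementedError("spatially constrained null not implemented")
    if null != "shuffle":
        raise ValueError(f"unknown null {null!r}")
    xv, yv = _aligned(x, y)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in a parcel vector")
    if method == "spearman":
        xv = stats.rankdata(xv)
        yv = stats.rankdata(yv)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xs = (xv - xv.mean()) / xv.std()
    ys = (yv - yv.mean()) / yv.std()
    P = len(xs)
    r_obs = float(xs @ ys / P)
    rng = np.random.default_rng(rng_seed)
    perms = rng.permuted(np.tile(ys, (n_perm, 1)), axis=1)
    r_null = perms @ xs / P
    b = int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12))
    return r_obs, (b + 1) / (n_perm + 1)


def fdr_across_maps(
    results: Sequence[SpatialCorrelationResult], q: float = 0.05
) -> list[SpatialCorrelationResult]:
    """Benjamini-Hochberg across the tracer family; attaches p_fdr and flags."""
    if not results:
        raise ValueError("need at least one result")
    p = np.array([r.p_perm for r in results])
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return [
        replace(r, p_fdr=float(pa), significant=bool(rej))
        for r, pa, rej in zip(results, p_adj, reject)
    ]


def neurochem_profile(
    network_input: Volume3D | ParcelVector,
    receptor_maps: Sequence[ReceptorMap],
    parcel_atlas: AtlasLabelMap | None = None,
    method: str = "spearman",
    n_perm: int = 5000,
    q: float = 0.05,
    rng_seed: int | None = None,
) -> list[SpatialCorrelationResult]:
    """Correlate a network map against a family of receptor maps.

    Parcellates volumetric inputs, runs the permutation test per tracer
    (each with a distinct child seed spawned from ``rng_seed``), and adjusts
    across the family by FDR.
    """
    if not receptor_maps:
        raise ValueError("need at least one receptor map")
    if isinstance(network_input, Volume3D):
        if parcel_atlas is None:
            raise ValueError("parcel_atlas required for volumetric input")
        net = parcellate(network_input, parcel_atlas)
    else:
        net = network_input
    seeds = np.random.SeedSequence(rng_seed).spawn(len(receptor_maps))
    results = []
    for rmap, child in zip(receptor_maps, seeds):
        vals = rmap.values
        if isinstance(vals, Volume3D):
            if parcel_atlas is None:
                raise ValueError("parcel_atlas required for volumetric receptor maps")
            vals = parcellate(vals, parcel_atlas)
        r_obs, p = permutation_test(
            net, vals, n_perm=n_perm,
            rng_seed=int(child.generate_state(1)[0] % (2**31)),
            method=method,
        )
        # report the conventional coefficient, not the rank-product shortcut
        r = spatial_correlation(net, vals, method=method)
        results.append(
            SpatialCorrelationResult(
                tracer_label=rmap.tracer_label,
                r=r,
                p_perm=p,
                n_parcels=len(np.intersect1d(net.parcel_ids, vals.parcel_ids)),
                method=method,
            )
        )
    return fdr_across_maps(results, q=q)


def results_to_frame(results: Sequence[SpatialCorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tracer": [r.tracer_label for r in results],
            "r": [r.r for r in results],
            "p_perm": [r.p_perm for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "significant": [r.significant for r in results],
            "n_parcels": [r.n_parcels for r in results],
            "method": [r.method for r in results],
        }
    )
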