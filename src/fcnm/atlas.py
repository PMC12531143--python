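"""Overlap between a network mask and a canonical network label atlas.

The overlap proportion for each canonical network is the share of THAT
network's voxels covered by the network mask (denominator = canonical
network size), reported as a percentage. A canonical network is called
"involved" when the proportion reaches an inclusive threshold, 20% by
default. A complementary diagnostic column — the fraction of the network
mask falling inside each label — is emitted alongside but plays no role in
the involvement call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkMask
from .volumes import BinaryMask, Volume3D, mm_to_voxel, voxel_centers_mm

__all__ = [
    "CANONICAL_NETWORK_NAMES",
    "AtlasLabelMap",
    "OverlapReport",
    "resample_labels_nearest",
    "overlap_proportions",
    "classify_involvement",
]

CANONICAL_NETWORK_NAMES: dict[int, str] = {
    1: "visual",
    2: "somatomotor",
    3: "dorsal_attention",
    4: "ventral_attention",
    5: "limbic",
    6: "frontoparietal",
    7: "default_mode",
    8: "subcortical",
}


@dataclass
class AtlasLabelMap:
    """Integer label volume plus label -> name table; 0 is background."""

    labels: Volume3D
    names: dict[int, str]

    def __post_init__(self) -> None:
        data = np.asarray(self.labels.data)
        if not np.allclose(data, np.rint(data)) or data.min() < 0:
            raise ValueError("atlas labels must be nonnegative integers")
        self.labels = Volume3D(
            np.rint(data).astype(int), self.labels.affine, self.labels.space_label
        )
        present = set(np.unique(self.labels.data)) - {0}
        missing = [lab for lab in self.names if lab not in present]
        if missing:
            raise ValueError(f"named labels absent from the grid: {missing}")

    def label_mask(self, label: int) -> BinaryMask:
        return BinaryMask(
            (self.labels.data == label).astype(np.uint8),
            self.labels.affine,
            self.labels.space_label,
        )


@dataclass
class OverlapReport:
    """Per-canonical-network overlap table with involvement calls."""

    table: pd.DataFrame  # columns: label, name, overlap_voxels, network_voxels,
    #          proportion_pct, network_inside_label_frac, involved
    threshold_pct: float | None = None

    def involved_networks(self) -> list[str]:
        if "involved" not in self.table:
            return []
        return list(self.table.loc[self.table["involved"], "name"])

    def to_json_dict(self) -> dict:
        return {
            "threshold_pct": self.threshold_pct,
            "networks": self.table.to_dict(orient="records"),
        }


def resample_labels_nearest(atlas: AtlasLabelMap, template: Volume3D) -> AtlasLabelMap:
    """Nearest-neighbor resampling of a label map onto a template grid.

    Each template voxel takes the label of the atlas voxel nearest (by
    rounding the mapped continuous index) to its center; labels stay
    categorical.
    """
    inv = np.linalg.inv(atlas.labels.affine)
    centers = voxel_centers_mm(template.shape, template.affine)
    homog = np.c_[centers, np.ones(len(centers))]
    idx = np.rint((inv @ homog.T).T[:, :3]).astype(int)
    shape = np.array(atlas.labels.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(centers), dtype=int)
    out[inside] = atlas.labels.data[tuple(idx[inside].T)]
    return AtlasLabelMap(
        Volume3D(out.reshape(template.shape), template.affine, template.space_label),
        dict(atlas.names),
    )


def overlap_proportions(network: NetworkMask, atlas: AtlasLabelMap) -> OverlapReport:
    """Overlap of the network mask with each named canonical network.

    proportion_pct = 100 * |network mask AND label| / |label|.
    Raises if a named label has zero voxels (atlas invariant violation).
    """
    if not network.mask.same_geometry(atlas.labels):
        raise ValueError("network mask and atlas must share geometry")
    net = network.mask.data.astype(bool)
    net_size = int(net.sum())
    rows = []
    for label, name in sorted(atlas.names.items()):
        lab = atlas.labels.data == label
        lab_size = int(lab.sum())
        if lab_size == 0:
            raise ValueError(f"label {label} ({name}) has zero voxels")
        inter = int((net & lab).sum())
        rows.append(
            {
                "label": label,
                "name": name,
                "overlap_voxels": inter,
                "network_voxels": lab_size,
                "proportion_pct": 100.0 * inter / lab_size,
                "network_inside_label_frac": (inter / net_size) if net_size else 0.0,
            }
        )
    return OverlapReport(table=pd.DataFrame(rows))


def classify_involvement(report: OverlapReport, threshold_pct: float = 20.0) -> OverlapReport:
    """Flag canonical networks with overlap proportion >= threshold (inclusive)."""
    table = report.table.copy()
    table["involved"] = table["proportion_pct"] >= threshold_pct - 1e-12
    return OverlapReport(table=table, threshold_pct=threshold_pct)
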