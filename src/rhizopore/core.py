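"""Shared containers for phase-labelled soil volumes.

A microcosm image is a 3D grid of integer phase labels at isotropic voxel
size.  Five phases occur: air-filled pores resolvable at the imaging
resolution, a "mixed" phase of sub-resolution water-filled pores plus
silt/clay particles, solid mineral grains, the root, and root hairs.
Arrays are stored in (z, y, x) order; physical distance is voxel index
difference times ``voxel_size`` (μm).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

# Phase label codes (8-bit).
PORE = 0
MIXED = 1
SOLID = 2
ROOT = 3
HAIR = 4

LABEL_NAMES = {PORE: "pore", MIXED: "mixed", SOLID: "solid", ROOT: "root", HAIR: "hair"}

#: array axis (z,y,x order) for each named spatial axis
AXIS_INDEX = {"z": 0, "y": 1, "x": 2}
AXIS_NAMES = {v: k for k, v in AXIS_INDEX.items()}


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class LabelledVolume:
    """Phase-labelled voxel grid with physical voxel size.

    Parameters
    ----------
    labels : ndarray of uint8, shape (nz, ny, nx)
        Phase codes restricted to {0=pore, 1=mixed, 2=solid, 3=root, 4=hair}.
    voxel_size : float
        Isotropic voxel edge length in μm.
    root_axis : str or None
        Named axis ('x', 'y' or 'z') the main root runs along, if a root
        is present.
    provenance : str
        Free-form origin record (generator config hash + seed, or file path).
    """

    labels: np.ndarray
    voxel_size: float
    root_axis: str | None = None
    provenance: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.labels.size == 0:
            raise ValueError("zero-sized volume rejected")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive (μm)")
        codes = np.unique(self.labels)
        bad = [int(c) for c in codes if int(c) not in LABEL_NAMES]
        if bad:
            raise ValueError(f"unknown label codes present: {bad}")
        if self.root_axis is not None and self.root_axis not in AXIS_INDEX:
            raise ValueError("root_axis must be one of 'x', 'y', 'z'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given phase codes."""
        return np.isin(self.labels, codes)

    def phase_fraction(self, code: int) -> float:
        return float(np.count_nonzero(self.labels == code)) / self.labels.size

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size * 1e-3) ** 3

    def copy(self) -> "LabelledVolume":
        return LabelledVolume(
            self.labels.copy(), self.voxel_size, self.root_axis, self.provenance
        )
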