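"""Volume and table I/O.

Labelled volumes are stored as multi-page 8-bit TIFF stacks (one page per
z-slice) with a JSON sidecar carrying the voxel size, axis order, label
map and provenance.  Tabular results are CSV with a header and
deterministic column order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import AXIS_INDEX, LABEL_NAMES, LabelledVolume

logger = logging.getLogger("rhizopore")

_CANONICAL_ORDER = "zyx"


@dataclass
class VolumeMetadata:
    """Sidecar metadata accompanying a label stack."""

    voxel_size: float
    axis_order: str = _CANONICAL_ORDER
    label_map: dict = None
    root_axis: str | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.label_map is None:
            self.label_map = {str(k): v for k, v in LABEL_NAMES.items()}
        if sorted(self.axis_order) != ["x", "y", "z"]:
            raise ValueError("axis_order must be a permutation of 'zyx'")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(volume: LabelledVolume, path) -> Path:
    """Write a labelled volume as an 8-bit TIFF stack plus JSON sidecar.

    Returns the sidecar path.  Round-trips bit-exactly with
    :func:`read_volume`.
    """
    path = Path(path)
    tifffile.imwrite(path, volume.labels.astype(np.uint8), photometric="minisblack")
    meta = VolumeMetadata(
        voxel_size=volume.voxel_size,
        axis_order=_CANONICAL_ORDER,
        root_axis=volume.root_axis,
        provenance=volume.provenance,
    )
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(asdict(meta), indent=2))
    logger.info("wrote volume %s (%s voxels)", path, volume.labels.shape)
    return sidecar


def read_volume(path, voxel_size: float | None = None) -> LabelledVolume:
    """Read a label stack and its sidecar back into a LabelledVolume.

    Without a sidecar an explicit ``voxel_size`` is required.  Unknown
    label codes (absent from the sidecar's label map) are rejected.  A
    stack stored in a non-canonical axis order is transposed back to
    (z, y, x) according to the sidecar.
    """
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = VolumeMetadata(**json.loads(sidecar.read_text()))
    elif voxel_size is not None:
        meta = VolumeMetadata(voxel_size=voxel_size)
    else:
        raise FileNotFoundError(
            f"missing sidecar {sidecar}: pass an explicit voxel_size (μm)"
        )
    known = {int(k) for k in meta.label_map}
    present = {int(c) for c in np.unique(labels)}
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(
            f"label codes {unknown} present in {path} but absent from the "
            f"label map {sorted(known)}"
        )
    if meta.axis_order != _CANONICAL_ORDER:
        perm = [meta.axis_order.index(a) for a in _CANONICAL_ORDER]
        labels = np.transpose(labels, perm)
    return LabelledVolume(
        labels=labels,
        voxel_size=meta.voxel_size,
        root_axis=meta.root_axis,
        provenance=meta.provenance or str(path),
    )


def write_table(records, path, columns=None) -> Path:
    """Write homogeneous records (or a DataFrame) as CSV with a header.

    Column order follows the first record (or ``columns``); an empty
    record list yields a header-only file.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        if columns is None and records:
            columns = list(records[0].keys())
        frame = pd.DataFrame(records, columns=columns)
    frame.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> Path:
    """JSON dump with numpy-aware conversion."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
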