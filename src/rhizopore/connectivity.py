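"""Pore-cluster connectivity and simulated-drying percolation analysis.

Connected pore clusters are labelled with the 18-neighbourhood (voxels
sharing a face or an edge).  Connectivity is summarised by the
dimensionless index

    Gamma_p = (1 / N_p^2) * sum_i v_i^2,

where v_i are cluster volumes and N_p the total pore volume: 1 for a
single cluster, 1/N for N equal clusters.  A drying experiment is
simulated by thresholding the local-thickness map at decreasing maximum
pore diameters (large pore bodies drain first) and re-evaluating Gamma_p
on each retained subset; a logistic curve

    Gamma_p(d) = Gamma_p,max / (1 + exp(-a (d - d0)))

fitted to the resulting curve locates the percolation threshold d0, the
maximum pore diameter at which connectivity collapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .geometry import PoreSizeMap

#: 18-connected structuring element (faces + edges, no corners)
STRUCTURE_18 = ndimage.generate_binary_structure(3, 2)


@dataclass
class ClusterLabelling:
    """Connected-component labelling of a binary mask under 18-connectivity."""

    labels: np.ndarray
    volumes: np.ndarray  # voxels per cluster, index 0 ↔ cluster id 1
    n_clusters: int
    total_volume: int

    def __post_init__(self):
        assert int(self.volumes.sum()) == self.total_volume


def label_pores(mask: np.ndarray) -> ClusterLabelling:
    """Label connected clusters of a binary mask (18-connectivity)."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=STRUCTURE_18)
    if n == 0:
        volumes = np.zeros(0, dtype=np.int64)
    else:
        volumes = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return ClusterLabelling(
        labels=labels,
        volumes=volumes,
        n_clusters=int(n),
        total_volume=int(mask.sum()),
    )


def gamma_index(labelling: ClusterLabelling) -> float:
    """Dimensionless connectivity index Gamma_p of a cluster labelling.

    Undefined (NaN) for an empty mask.
    """
    if labelling.total_volume == 0:
        return float("nan")
    v = labelling.volumes.astype(float)
    return float(np.sum(v * v) / labelling.total_volume**2)


@dataclass
class ConnectivityCurve:
    """Gamma_p as a function of the maximum retained pore diameter.

    ``diameters_um`` is strictly decreasing; ``gamma`` entries are NaN
    where the retained set is empty.  ``gamma_max`` is the connectivity of
    the full pore space.
    """

    diameters_um: np.ndarray
    gamma: np.ndarray
    gamma_max: float

    def valid(self):
        keep = np.isfinite(self.gamma)
        return self.diameters_um[keep], self.gamma[keep]


def drying_curve(size_map: PoreSizeMap, step: float = 10.0) -> ConnectivityCurve:
    """Simulated-drying connectivity curve from a local-thickness map.

    Thresholds run downward from the maximum pore diameter (rounded up to
    the nearest ``step``) in decrements of ``step`` μm; at each threshold d
    only pore voxels with local diameter ≤ d are retained (pores wider
    than d have drained), re-labelled and summarised by Gamma_p.  The
    first entry equals Gamma_p of the full pore space.
    """
    if step <= 0:
        raise ValueError("drying step must be positive (μm)")
    if not size_map.pore_mask().any():
        raise ValueError("empty pore space has no drying curve")
    diam = size_map.diameter_um
    top = float(np.ceil(size_map.max_diameter / step) * step)
    thresholds = np.arange(top, 0.0, -step)
    gammas = np.empty(thresholds.size)
    for i, d in enumerate(thresholds):
        retained = (diam > 0) & (diam <= d + 1e-9)
        gammas[i] = gamma_index(label_pores(retained))
    return ConnectivityCurve(
        diameters_um=thresholds, gamma=gammas, gamma_max=float(gammas[0])
    )


@dataclass
class PercolationFit:
    """Logistic fit of a connectivity curve.

    The logistic value at ``d0`` is ``gamma_max / 2``; ``gamma_max`` is
    fixed to the measured full-pore-space connectivity during fitting.
    ``degenerate`` marks curves with no connectivity breakdown (no finite
    threshold).
    """

    gamma_max: float
    a: float
    d0: float
    rmse: float
    degenerate: bool = False

    def predict(self, d):
        d = np.asarray(d, dtype=float)
        return self.gamma_max / (1.0 + np.exp(-self.a * (d - self.d0)))


def fit_percolation(curve: ConnectivityCurve) -> PercolationFit:
    """Least-squares logistic fit locating the percolation threshold d0.

    Requires ≥ 4 valid curve points.  Curves that never drop appreciably
    below Gamma_p,max are flagged degenerate (d0, a = NaN).
    """
    d, g = curve.valid()
    if d.size < 4:
        raise ValueError("percolation fit requires at least 4 valid points")
    gamma_max = curve.gamma_max
    if np.all(g > 0.99 * gamma_max) or np.ptp(g) < 1e-3 * max(gamma_max, 1e-12):
        return PercolationFit(gamma_max, float("nan"), float("nan"), 0.0, True)

    def model(x, a, d0):
        return gamma_max / (1.0 + np.exp(-a * (x - d0)))

    # initial guesses: midpoint crossing and a slope spanning the d-range
    d0_init = float(d[np.argmin(np.abs(g - gamma_max / 2.0))])
    a_init = 4.0 / max(float(np.ptp(d)), 1e-9)
    try:
        popt, _ = optimize.curve_fit(
            model,
            d,
            g,
            p0=[a_init, d0_init],
            bounds=([1e-9, -np.inf], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"percolation fit did not converge: {err}") from err
    a_fit, d0_fit = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((model(d, a_fit, d0_fit) - g) ** 2)))
    return PercolationFit(gamma_max, a_fit, d0_fit, rmse, False)
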