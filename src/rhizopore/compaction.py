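"""Root-compaction porosity model and group-comparison statistics.

The compaction model is the classical exponential description of soil
deformation around a cylindrical root: porosity recovers from a (low)
value at the root surface towards the undisturbed bulk value with an
e-folding distance proportional to the root radius,

    phi(x) = phi_s + (phi_b - phi_s) * (1 - exp(-x / (k_D * r))),

where ``x`` is distance from the root surface (μm), ``r`` the root radius
(μm), ``phi_b`` the bulk porosity, ``phi_s`` the porosity at the root
surface and ``k_D`` a dimensionless soil mechanical parameter.

The surface porosity is not observable below the imaging resolution, so it
is fixed by rule rather than measured:

``"zero"`` (default)
    Full compaction at the wall, phi_s = 0.  Valid for any parameter set.
``"conservation"``
    phi_s chosen so the integrated porosity deficit around the root equals
    the root cross-section (all displaced volume accommodated by pore
    loss):  phi_b - phi_s = 1 / (2 k_D (1 + k_D)).  For small k_D this
    implies a negative phi_s and is rejected.

The statistics layer bundles the comparisons used throughout the pipeline:
a normality pre-check (Shapiro–Wilk) choosing one-way ANOVA vs
Kruskal–Wallis, Dunn pairwise post hoc tests with Bonferroni correction,
and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Dexter-type compaction model
# ---------------------------------------------------------------------------

@dataclass
class DexterParameters:
    """Parameters of the exponential root-compaction porosity model.

    ``surface_porosity`` may be given explicitly; when None it is derived
    according to ``surface_rule``.
    """

    bulk_porosity: float
    root_radius: float  # μm
    k_D: float
    surface_porosity: float | None = None
    surface_rule: str = "zero"

    def __post_init__(self):
        if not (0.0 <= self.bulk_porosity <= 1.0):
            raise ValueError("bulk_porosity must lie in [0, 1]")
        if self.root_radius <= 0:
            raise ValueError("root_radius must be positive (μm)")
        if self.k_D <= 0:
            raise ValueError("k_D must be positive")
        if self.surface_porosity is None:
            if self.surface_rule == "zero":
                self.surface_porosity = 0.0
            elif self.surface_rule == "conservation":
                deficit = 1.0 / (2.0 * self.k_D * (1.0 + self.k_D))
                self.surface_porosity = self.bulk_porosity - deficit
            else:
                raise ValueError(f"unknown surface_rule {self.surface_rule!r}")
        if self.surface_porosity < 0:
            raise ValueError(
                "surface porosity below 0: compaction parameters imply a "
                "porosity deficit larger than the bulk porosity"
            )
        if self.surface_porosity > self.bulk_porosity:
            raise ValueError("surface_porosity must not exceed bulk_porosity")

    @property
    def decay_length(self) -> float:
        """e-folding distance of porosity recovery, k_D * root_radius (μm)."""
        return self.k_D * self.root_radius


def dexter_porosity(x, params: DexterParameters):
    """Predicted pore volume fraction at distance ``x`` (μm) from the root surface.

    Accepts a scalar or array of non-negative distances.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance from root surface must be non-negative")
    phi_s = params.surface_porosity
    phi_b = params.bulk_porosity
    out = phi_s + (phi_b - phi_s) * (1.0 - np.exp(-x / params.decay_length))
    return float(out) if out.ndim == 0 else out


def displaced_volume_balance(params: DexterParameters, x_max: float = None, n: int = 200_000):
    """Integrated porosity deficit around the root vs the root cross-section.

    Returns ``(integral, root_area)`` where the integral is
    ∫ (phi_b - phi(x)) 2π (r + x) dx over [0, x_max], in μm² (per unit root
    length).  Under the "conservation" surface rule the two agree.
    """
    r = params.root_radius
    if x_max is None:
        x_max = 60.0 * params.decay_length
    x = np.linspace(0.0, x_max, n)
    deficit = params.bulk_porosity - dexter_porosity(x, params)
    integral = float(np.trapezoid(deficit * 2.0 * np.pi * (r + x), x))
    return integral, float(np.pi * r * r)


# ---------------------------------------------------------------------------
# Measured-vs-predicted profile comparison
# ---------------------------------------------------------------------------

@dataclass
class ProfileComparison:
    distance_um: np.ndarray
    measured: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray
    rmse: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_um": self.distance_um,
                "measured": self.measured,
                "predicted": self.predicted,
                "residual": self.residuals,
            }
        )


def compare_profiles(measured_profile, params: DexterParameters, phase: str = "pore") -> ProfileComparison:
    """Residuals between a measured annulus profile and the compaction model.

    ``measured_profile`` is an AnnulusProfile (geometry module); the model is
    evaluated at annulus midpoints.  Annuli with missing fractions are
    dropped.
    """
    dist = np.asarray(measured_profile.midpoint_um, dtype=float)
    measured = np.asarray(measured_profile.fractions[phase], dtype=float)
    keep = np.isfinite(measured)
    dist, measured = dist[keep], measured[keep]
    if dist.size == 0:
        raise ValueError("no valid annuli to compare")
    predicted = dexter_porosity(dist, params)
    residuals = measured - predicted
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return ProfileComparison(dist, measured, predicted, residuals, rmse)


def compare_profile_to_curve(measured_profile, predicted, phase: str = "pore") -> ProfileComparison:
    """As :func:`compare_profiles` but against an explicit predicted curve
    sampled on the same annulus grid."""
    dist = np.asarray(measured_profile.midpoint_um, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != dist.shape:
        raise ValueError("predicted curve does not share the annulus grid")
    measured = np.asarray(measured_profile.fractions[phase], dtype=float)
    keep = np.isfinite(measured)
    residuals = measured[keep] - predicted[keep]
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return ProfileComparison(dist[keep], measured[keep], predicted[keep], residuals, rmse)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    pvalue: float
    normality_pvalues: dict
    pairwise: pd.DataFrame
    alpha: float

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def _dunn_pairwise(groups: dict, alpha: float) -> pd.DataFrame:
    """Dunn's rank-based pairwise tests with Bonferroni correction.

    Uses pooled mid-ranks with the standard tie correction
    Σ(t³ − t) / (12 (N − 1)) subtracted from N(N+1)/12.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for g in names:
        mean_ranks[g] = float(np.mean(ranks[start : start + sizes[g]]))
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "alpha_per_pair": alpha / m,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def group_compare(groups: dict, alpha: float = 0.05) -> GroupComparison:
    """Omnibus comparison of ≥2 groups with a normality pre-check.

    Shapiro–Wilk is run per group at the same alpha; if every group is
    consistent with normality the omnibus test is one-way ANOVA, otherwise
    Kruskal–Wallis.  Dunn–Bonferroni pairwise tests are always reported.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float).ravel() for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    normality = {}
    for g, v in arrays.items():
        if v.size >= 3 and np.ptp(v) > 0:
            normality[g] = float(stats.shapiro(v).pvalue)
        else:
            normality[g] = np.nan
    all_normal = all(p > alpha for p in normality.values() if np.isfinite(p))
    samples = list(arrays.values())
    if np.ptp(np.concatenate(samples)) == 0:
        # all observations identical: no evidence of difference
        test_name = "degenerate"
        statistic, pvalue = 0.0, 1.0
    elif all_normal:
        test_name = "anova"
        res = stats.f_oneway(*samples)
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    else:
        test_name = "kruskal-wallis"
        res = stats.kruskal(*samples)
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    pairwise = _dunn_pairwise(arrays, alpha)
    return GroupComparison(test_name, statistic, pvalue, normality, pairwise, alpha)


def pearson(x, y):
    """Pearson correlation coefficient and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have matching shape")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
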