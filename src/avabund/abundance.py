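"""From imputed grid densities to species-level abundance distributions.

Each species' imputed log10 densities are pooled across grids (weighted
by reporting rate, the fraction of a grid's checklists recording the
species) and across imputations (Rubin-style), capped by a conservative
SE ceiling, converted to an area via its sampled grid cells or known
range, and finally expanded into a simulated distribution of global
abundances: 10^Normal(mean, se) times area, with the median taken as the
species' global population estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import as_rng

#: conservative cap on the pooled log10-density SE, 1 log10 unit;
#: implies an upper 95% limit 10^1.96 ~ 91x the point density.
SE_CEILING = 1.0


@dataclass
class DensityEstimate:
    species_id: str
    mean_log10_density: float
    se_log10_density: float
    n_grids: int
    area_km2: float
    area_source: str  # grids | range_clip | range_expand | grids_no_range


@dataclass
class AbundanceDistribution:
    """Sorted simulated abundances for one species."""

    species_id: str
    draws: np.ndarray  # ascending
    median: float
    ci95: tuple[float, float]

    @classmethod
    def from_draws(cls, species_id: str, draws: np.ndarray
                   ) -> "AbundanceDistribution":
        d = np.sort(np.asarray(draws, dtype=float))
        return cls(species_id, d, float(np.median(d)),
                   (float(np.quantile(d, 0.025)), float(np.quantile(d, 0.975))))


def weighted_density(
    densities: np.ndarray,
    ses: np.ndarray,
    reporting_rates: np.ndarray,
) -> tuple[float, float, float]:
    """Pool per-grid imputed densities into one log10 density.

    ``densities`` and ``ses`` are (m imputations x n grids); weights are
    the grid reporting rates, normalized.  Returns (weighted mean log10
    density, between-imputation variance of that mean including the
    finite-m correction (1 + 1/m), weighted mean of the imputed SEs).
    """
    d = np.atleast_2d(np.asarray(densities, dtype=float))
    s = np.atleast_2d(np.asarray(ses, dtype=float))
    w = np.asarray(reporting_rates, dtype=float).copy()
    if d.shape[1] != w.size:
        raise ValueError("weights must match the number of grids")
    if w.sum() <= 0:
        warnings.warn("all reporting-rate weights zero; using uniform weights")
        w = np.ones_like(w)
    w = w / w.sum()
    per_imp = d @ w  # weighted mean per imputation
    mean = float(per_imp.mean())
    m = d.shape[0]
    between = float(per_imp.var(ddof=1)) * (1.0 + 1.0 / m) if m > 1 else 0.0
    mean_se = float((s @ w).mean())
    return mean, between, mean_se


def pool_se(
    between_imputation_variance: float,
    weighted_mean_se: float,
    ceiling: float = SE_CEILING,
    soft: bool = False,
) -> float:
    """Total log10-density SE: imputation spread plus average imputed SE.

    se = sqrt(V_between + mean_se^2), limited by ``ceiling``.  The default
    is a hard cap at 1 log10 unit; ``soft`` applies shrinkage
    se^2 -> se^2 / (1 + se^2 / ceiling^2) instead.
    """
    if between_imputation_variance < 0 or weighted_mean_se < 0:
        raise ValueError("variance inputs must be nonnegative")
    var = between_imputation_variance + weighted_mean_se ** 2
    if soft:
        return float(np.sqrt(var / (1.0 + var / ceiling ** 2)))
    return float(min(np.sqrt(var), ceiling))


def species_area(
    sampled_cell_areas: np.ndarray,
    range_area_km2: float | None = None,
    sampled_cells: set | None = None,
    range_cells: set | None = None,
    coverage_threshold: float = 0.95,
) -> tuple[float, str]:
    """Choose the area a species' density is scaled by.

    Defaults to the summed area of the sampled grid cells; a known range
    overrides it when the range is smaller (``range_clip``) or when the
    sampled cells cover less than ``coverage_threshold`` of the range's
    cells (``range_expand`` — sampling gaps mean the grid area
    underestimates the true extent).  A missing or nonpositive range falls
    back to the grid area, flagged ``grids_no_range``.
    """
    areas = np.asarray(sampled_cell_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("species has no sampled cells")
    grid_area = float(areas.sum())
    if range_area_km2 is None or not np.isfinite(range_area_km2) \
            or range_area_km2 <= 0:
        if range_area_km2 is not None:
            warnings.warn("nonpositive range area treated as unknown")
        return grid_area, "grids_no_range"
    if range_area_km2 < grid_area:
        return float(range_area_km2), "range_clip"
    if sampled_cells is not None and range_cells:
        coverage = len(set(sampled_cells) & set(range_cells)) / len(range_cells)
        if coverage < coverage_threshold:
            return float(range_area_km2), "range_expand"
    return grid_area, "grids"


def simulate_abundance(
    mean_log10_density: float,
    se: float,
    area_km2: float,
    n_draws: int = 10000,
    seed=None,
    species_id: str = "",
) -> AbundanceDistribution:
    """Simulate the species' global abundance distribution.

    draws = 10^Normal(mean, se) * area, sorted ascending; the median is
    the global population estimate, the 2.5/97.5% quantiles its 95% CI.
    """
    if se < 0:
        raise ValueError("se must be nonnegative")
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    rng = as_rng(seed)
    log_d = rng.normal(mean_log10_density, se, size=n_draws) if se > 0 \
        else np.full(n_draws, mean_log10_density)
    draws = 10.0 ** log_d * area_km2
    return AbundanceDistribution.from_draws(species_id, draws)
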