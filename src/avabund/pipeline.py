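"""End-to-end orchestration: synthetic world in, abundance estimates out.

The five pipeline stages mirror the data-integration design: (1) fit the
measurement-error regression on expert regional densities vs checklist
relative abundance; (2) compute relative abundance per species x 5-degree
grid cell; (3) attach detectability-related traits; (4) impute missing
densities by two-level chained PMM; (5) pool densities, scale by area and
simulate per-species abundance distributions.  The leave-one-out harness
replays stages 1–5 with one training species withheld to measure how well
the imputation recovers it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abundance as ab
from ._utils import spawn_rngs
from .imputation import assemble_imputation_table, run_chained_imputation
from .regression import (MeasurementErrorRegression, build_training_table,
                         fit_measurement_error_model)
from .relabund import (ChecklistTable, GridSpec, assign_and_select_grids,
                       filter_checklists, rel_abund_se,
                       relative_abundance_table)
from .synthetic import (ExpertEstimateTable, SyntheticWorld, apply_missingness,
                        default_effort, make_expert_estimates,
                        simulate_checklists)

#: per-variable missing fractions emulating real trait coverage
DEFAULT_MISSING_RATES = {"iucn_ordinal": 0.08, "body_mass_g": 0.16,
                         "dist_from_brown": 0.40, "brightness": 0.40}


@dataclass
class PipelineConfig:
    """Desk-scale defaults for the full run (reduced MCMC, m = 10)."""

    min_checklists: int = 50
    train_fraction: float = 0.3
    noise_sd_log10: float = 0.5
    mcmc_iterations: int = 3000
    mcmc_chains: int = 2
    mcmc_warmup: int = 1000
    m_imputations: int = 10
    maxit: int = 3
    donors: int = 5
    n_draws: int = 10000
    zero_se: float = 0.5
    rho: float = -1.0
    trait_missing_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))


@dataclass
class PipelineResult:
    config: PipelineConfig
    grid: GridSpec
    relabund: pd.DataFrame
    training: pd.DataFrame
    traits: pd.DataFrame  # with injected missingness
    model: MeasurementErrorRegression
    imputation_table: pd.DataFrame
    estimates: pd.DataFrame
    distributions: list[ab.AbundanceDistribution]
    range_area_km2: pd.Series
    range_cells: dict

    def distribution(self, species_id: str) -> ab.AbundanceDistribution:
        for d in self.distributions:
            if d.species_id == species_id:
                return d
        raise KeyError(species_id)


def region_relative_abundance(
    checklists: ChecklistTable,
    expert: ExpertEstimateTable,
) -> pd.DataFrame:
    """Relative abundance (and log10 SE) per expert region.

    RA is the month-first mean over the region's checklists; the SE is
    computed per species from the scatter of all its month x region mean
    estimates, then delta-method converted to the log10 scale.
    """
    ev = checklists.events
    counts = checklists.counts
    rows = []
    strata: dict[str, list[float]] = {}
    n_lists: dict[str, int] = {}
    for (sp, region), cells in (
            ((r.species_id, r.region_id), expert.region_cells[r.region_id])
            for r in expert.table.itertuples()):
        ev_r = ev[ev["grid_id"].isin(cells)]
        if ev_r.empty:
            rows.append((sp, region, 0.0, np.nan))
            continue
        eff = ev_r.groupby("month").size()
        sub = counts[(counts["species_id"] == sp)
                     & counts["checklist_id"].isin(set(ev_r["checklist_id"]))]
        sub = sub.merge(ev_r[["checklist_id", "month"]], on="checklist_id")
        monthly = sub.groupby("month")["count"].sum() \
            .reindex(eff.index, fill_value=0)
        means = (monthly / eff).to_numpy(dtype=float)
        rows.append((sp, region, float(means.mean()), np.nan))
        strata.setdefault(sp, []).extend(means.tolist())
        n_lists[sp] = n_lists.get(sp, 0) + int(len(ev_r))
    out = pd.DataFrame(rows, columns=["species_id", "region_id", "rel_abund",
                                      "se_log10"])
    for sp, means in strata.items():
        pos = np.asarray(means)
        if pos.mean() > 0:
            se = rel_abund_se(pos, n_checklists=n_lists[sp])
            out.loc[out["species_id"] == sp, "se_log10"] = se
    return out


def estimate_abundances(
    completed,
    relabund_records: pd.DataFrame,
    grid: GridSpec,
    range_area_km2: pd.Series | None,
    range_cells: dict | None,
    n_draws: int = 10000,
    seed: int = 0,
    species_subset=None,
) -> tuple[pd.DataFrame, list[ab.AbundanceDistribution]]:
    """Stage 5: pooled density -> area -> simulated abundance, per species."""
    ra = relabund_records.set_index(["species_id", "grid_id"]).sort_index()
    base = completed.datasets[0]
    species = (sorted(set(species_subset)) if species_subset is not None
               else sorted(base["species_id"].unique()))
    rngs = spawn_rngs(seed, len(species))
    rows, dists = [], []
    dens_stack = np.stack([d["density_log10"].to_numpy() for d in completed.datasets])
    se_stack = np.stack([d["density_se"].to_numpy() for d in completed.datasets])
    sp_col = base["species_id"].to_numpy()
    grid_col = base["grid_id"].to_numpy()
    for sp, rng in zip(species, rngs):
        sel = sp_col == sp
        cells = grid_col[sel]
        rr = ra.loc[sp].loc[cells, "reporting_rate"].to_numpy()
        mean, between, mean_se = ab.weighted_density(
            dens_stack[:, sel], se_stack[:, sel], rr)
        se = ab.pool_se(between, mean_se)
        cell_areas = grid.cell_area_km2(cells)
        r_area = (float(range_area_km2.get(sp, np.nan))
                  if range_area_km2 is not None else None)
        r_cells = range_cells.get(sp) if range_cells else None
        area, source = ab.species_area(
            cell_areas, None if r_area is None or np.isnan(r_area) else r_area,
            sampled_cells=set(cells.tolist()),
            range_cells=set(r_cells) if r_cells else None)
        dist = ab.simulate_abundance(mean, se, area, n_draws=n_draws,
                                     seed=rng, species_id=sp)
        rows.append((sp, mean, se, len(cells), area, source,
                     dist.median, dist.ci95[0], dist.ci95[1]))
        dists.append(dist)
    est = pd.DataFrame(rows, columns=[
        "species_id", "mean_log10_density", "se_log10_density", "n_grids",
        "area_km2", "area_source", "median", "lcl95", "ucl95"])
    return est, dists


def run_pipeline(
    world: SyntheticWorld,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run all five stages on a synthetic world."""
    config = config or PipelineConfig()
    seeds = [int(r.integers(2**31 - 1)) for r in spawn_rngs(seed, 8)]

    effort = default_effort(world, seed=seeds[0])
    checklists = simulate_checklists(world, effort, seed=seeds[1])
    filtered = filter_checklists(checklists)
    gridded, eligible, _ = assign_and_select_grids(
        filtered, world.grid, min_checklists=config.min_checklists)
    ra = relative_abundance_table(gridded, eligible)

    expert = make_expert_estimates(
        world, train_fraction=config.train_fraction,
        noise_sd_log10=config.noise_sd_log10, seed=seeds[2])
    region_ra = region_relative_abundance(gridded, expert)
    training = build_training_table(expert.table, region_ra,
                                    zero_se=config.zero_se)
    model = fit_measurement_error_model(
        training, iterations=config.mcmc_iterations, chains=config.mcmc_chains,
        warmup=config.mcmc_warmup, seed=seeds[3])

    traits = apply_missingness(world.traits, config.trait_missing_rates,
                               seed=seeds[4])
    # training species must also survive the grid-eligibility filters
    usable = model.coef_table_[
        model.coef_table_["species_id"].isin(set(ra["species_id"]))]
    table = assemble_imputation_table(ra, traits, usable, rho=config.rho)
    completed = run_chained_imputation(
        table, m=config.m_imputations, maxit=config.maxit,
        donors=config.donors, seed=seeds[5])

    estimates, dists = estimate_abundances(
        completed, ra, world.grid, world.range_area_km2, world.range_cells,
        n_draws=config.n_draws, seed=seeds[6])
    return PipelineResult(
        config=config, grid=world.grid, relabund=ra, training=training,
        traits=traits, model=model, imputation_table=table,
        estimates=estimates, distributions=dists,
        range_area_km2=world.range_area_km2, range_cells=world.range_cells)


def evaluate_recovery(result: PipelineResult, truth: pd.Series) -> dict:
    """Compare estimated abundances against the world's ground truth."""
    est = result.estimates.set_index("species_id")
    common = est.index.intersection(truth.index)
    est = est.loc[common]
    t = truth.loc[common].to_numpy(dtype=float)
    covered = (est["lcl95"].to_numpy() <= t) & (t <= est["ucl95"].to_numpy())
    log_err = np.log10(est["median"].to_numpy()) - np.log10(t)
    return {
        "n_species": int(len(common)),
        "coverage95": float(covered.mean()),
        "median_abs_log10_error": float(np.median(np.abs(log_err))),
        "log10_errors": log_err,
    }


def loo_species_validation(
    result: PipelineResult,
    species_id: str,
    m_small: int = 10,
    seed: int = 0,
    mcmc_iterations: int | None = None,
) -> dict:
    """Withhold one training species and replay the workflow.

    The regression is refit without the species' training rows, the
    imputation table rebuilt (so its density cells become missing), and
    ``m_small`` imputations drawn.  Reports per-row coverage of the
    species' full-model densities by the imputation range and by the
    0.05–0.95 quantile band, plus the withheld vs full median abundance.
    """
    if species_id not in set(result.training["species_id"]):
        raise ValueError(f"{species_id} is not a training species")
    cfg = result.config
    seeds = [int(r.integers(2**31 - 1)) for r in spawn_rngs(seed, 3)]
    training_wo = result.training[result.training["species_id"] != species_id]
    iters = mcmc_iterations or cfg.mcmc_iterations
    model = fit_measurement_error_model(
        training_wo, iterations=iters, chains=cfg.mcmc_chains,
        warmup=min(cfg.mcmc_warmup, iters // 3), seed=seeds[0])
    ra = result.relabund
    usable = model.coef_table_[
        model.coef_table_["species_id"].isin(set(ra["species_id"]))]
    table = assemble_imputation_table(ra, result.traits, usable, rho=cfg.rho)
    completed = run_chained_imputation(
        table, m=m_small, maxit=cfg.maxit, donors=cfg.donors, seed=seeds[1])

    sel = (table["species_id"] == species_id).to_numpy()
    observed = result.imputation_table.loc[
        result.imputation_table["species_id"] == species_id,
        "density_log10"].to_numpy()
    imputed = np.stack([d.loc[sel, "density_log10"].to_numpy()
                        for d in completed.datasets])  # (m_small, n_rows)
    lo, hi = imputed.min(axis=0), imputed.max(axis=0)
    q05 = np.quantile(imputed, 0.05, axis=0)
    q95 = np.quantile(imputed, 0.95, axis=0)
    in_range = (lo <= observed) & (observed <= hi)
    in_band = (q05 <= observed) & (observed <= q95)

    est, _ = estimate_abundances(
        completed, ra, result.grid, result.range_area_km2, result.range_cells,
        n_draws=cfg.n_draws, seed=seeds[2], species_subset=[species_id])
    full_median = float(result.estimates.set_index("species_id")
                        .loc[species_id, "median"])
    return {
        "species_id": species_id,
        "n_rows": int(sel.sum()),
        "range_coverage": float(in_range.mean()),
        "band_coverage": float(in_band.mean()),
        "withheld_median": float(est["median"].iloc[0]),
        "full_median": full_median,
    }
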