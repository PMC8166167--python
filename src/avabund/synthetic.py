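"""Ground-truthed synthetic world for the abundance-estimation pipeline.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for — semi-structured citizen-science checklists,
a small set of expert regional population estimates, detection-relevant
life-history traits, range areas and a species phylogeny — while keeping
exact per-species ground truth so every downstream stage can be verified
by parameter recovery.

Detection follows a species-specific log-linear law: the expected count
per checklist in a cell with true density d (individuals/km^2) is
10^(b_s + m_s * log10 d).  Trait–coefficient correlations are induced with
the signs and magnitudes observed in real detectability work (body mass
strongly negative on the intercept, colour weakly positive, flock size
weakly positive on the slope); threat status tracks true rarity.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._utils import as_rng, spawn_rngs
from .phylo import PhyloVCV
from .relabund import ChecklistTable, GridSpec

REALMS = ["westland", "meridia", "eastmarch", "borealia"]
GUILDS = ["invertivore", "granivore", "frugivore", "omnivore", "nectarivore"]

TRAIT_COLUMNS = ["body_mass_g", "flock_size", "brightness", "dist_from_brown",
                 "iucn_ordinal"]


@dataclass
class WorldConfig:
    """Knobs of the synthetic world (the defaults define the standard world).

    Densities are log10 individuals per km^2; the between-species law is
    log-normal (mean -1, SD 1 on the log10 scale), giving the right-skewed
    natural-scale global abundance distribution real avifaunas show.
    Detection slopes sit near 1 with small spread so log relative abundance
    is approximately a shifted log density.
    """

    n_species: int = 200
    n_grid_rows: int = 6
    n_grid_cols: int = 8
    cell_deg: float = 5.0
    lat0: float = -15.0
    lon0: float = 0.0
    # density surface
    mean_log10_density: float = -1.0
    sd_log10_density: float = 1.0
    spatial_sd: float = 0.3
    # occupancy: fraction of cells occupied per species ~ Beta(a, b)
    occupancy_beta: tuple[float, float] = (1.2, 3.5)
    # detection coefficients
    intercept_mean: float = 0.7
    intercept_sd: float = 0.35
    slope_mean: float = 1.0
    slope_sd: float = 0.06
    r_mass_intercept: float = -0.467
    r_brightness_intercept: float = 0.145
    r_brown_intercept: float = 0.101
    r_flock_slope: float = 0.146
    # traits
    log10_mass_mean: float = 1.5
    log10_mass_sd: float = 0.5
    # count law
    overdispersion: float | None = None  # NB size parameter; None = Poisson
    # checklist effort defaults
    checklists_per_month: float = 80.0
    effort_lognorm_sd: float = 0.6
    frac_incomplete: float = 0.10
    frac_short: float = 0.05
    frac_long: float = 0.05
    frac_far: float = 0.05

    def grid(self) -> GridSpec:
        return GridSpec(self.n_grid_rows, self.n_grid_cols, self.cell_deg,
                        self.lat0, self.lon0)


@dataclass
class ExpertEstimateTable:
    """Noisy regional population estimates for the training species."""

    table: pd.DataFrame  # species_id, region_id, abundance_estimate, region_area_km2
    region_cells: dict[str, list[int]]  # region_id -> grid cells


@dataclass
class SyntheticWorld:
    """A drawn world: everything the pipeline sees, plus ground truth."""

    config: WorldConfig
    species_ids: list[str]
    grid: GridSpec
    true_log10_density: pd.DataFrame  # species_id, grid_id, log10_density
    detect: pd.DataFrame  # species_id, detect_intercept, detect_slope
    traits: pd.DataFrame  # species_id + TRAIT_COLUMNS
    grouping: pd.DataFrame  # species_id, genus, family, order, realm, guild
    range_cells: dict[str, list[int]]
    range_area_km2: pd.Series
    tree: dendropy.Tree = field(repr=False)
    true_global_abundance: pd.Series = field(repr=False)

    def cell_density(self) -> pd.DataFrame:
        return self.true_log10_density


def _yule_tree(species_ids: list[str], rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth tree over the species, scaled to unit root depth."""
    pyrng = _random.Random(int(rng.integers(2**31 - 1)))
    taxa = dendropy.TaxonNamespace(species_ids)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0,
        num_extant_tips=len(species_ids),
        taxon_namespace=taxa, rng=pyrng)
    depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= depth
    return tree


def _nested_taxonomy(n: int, rng: np.random.Generator) -> pd.DataFrame:
    n_orders = max(2, n // 25)
    order_of_family: dict[int, int] = {}
    family_of_genus: dict[int, int] = {}
    orders = rng.integers(0, n_orders, size=n)
    fams = np.empty(n, dtype=int)
    gens = np.empty(n, dtype=int)
    for i in range(n):
        o = orders[i]
        f = o * 3 + rng.integers(0, 3)
        g = f * 3 + rng.integers(0, 3)
        order_of_family[f] = o
        family_of_genus[g] = f
        fams[i], gens[i] = f, g
    return pd.DataFrame({
        "genus": [f"gen{g:03d}" for g in gens],
        "family": [f"fam{f:03d}" for f in fams],
        "order": [f"ord{o:02d}" for o in orders],
    })


def generate_world(config: WorldConfig | None = None, seed: int = 0
                   ) -> SyntheticWorld:
    """Draw a complete synthetic world; bit-reproducible for a given seed."""
    config = config or WorldConfig()
    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    grid = config.grid()  # validates dimensions
    (rng_tr, rng_occ, rng_den, rng_tree, rng_grp) = spawn_rngs(seed, 5)

    n = config.n_species
    species_ids = [f"sp{i:04d}" for i in range(n)]

    # --- traits and detection coefficients (shared latent structure) ---
    z_mass = rng_tr.standard_normal(n)
    z_flock = rng_tr.standard_normal(n)
    z_bright = rng_tr.standard_normal(n)
    z_brown = rng_tr.standard_normal(n)
    z_b = rng_tr.standard_normal(n)
    z_m = rng_tr.standard_normal(n)

    body_mass_g = 10 ** (config.log10_mass_mean + config.log10_mass_sd * z_mass)
    flock_size = 1.0 + np.exp(0.8 * z_flock)
    brightness = 50.0 + 15.0 * z_bright
    dist_from_brown = 30.0 + 10.0 * z_brown

    r1, r2, r3 = (config.r_mass_intercept, config.r_brightness_intercept,
                  config.r_brown_intercept)
    resid = np.sqrt(max(1e-9, 1 - r1**2 - r2**2 - r3**2))
    detect_intercept = config.intercept_mean + config.intercept_sd * (
        r1 * z_mass + r2 * z_bright + r3 * z_brown + resid * z_b)
    rf = config.r_flock_slope
    detect_slope = config.slope_mean + config.slope_sd * (
        rf * z_flock + np.sqrt(1 - rf**2) * z_m)

    # --- ranges and the density surface ---
    a, b = config.occupancy_beta
    frac = rng_occ.beta(a, b, size=n)
    n_cells = np.maximum(1, np.round(frac * grid.n_cells).astype(int))
    range_cells = {sp: sorted(rng_occ.choice(grid.n_cells, size=k, replace=False))
                   for sp, k in zip(species_ids, n_cells)}

    mean_density = (config.mean_log10_density
                    + config.sd_log10_density * rng_den.standard_normal(n))
    rows = []
    for i, sp in enumerate(species_ids):
        cells = range_cells[sp]
        d = mean_density[i] + config.spatial_sd * rng_den.standard_normal(len(cells))
        for g, dg in zip(cells, d):
            rows.append((sp, g, dg))
    density = pd.DataFrame(rows, columns=["species_id", "grid_id", "log10_density"])

    areas = grid.cell_area_km2(density["grid_id"].to_numpy())
    density["cell_area_km2"] = areas
    density["cell_abundance"] = 10 ** density["log10_density"] * areas
    truth = density.groupby("species_id")["cell_abundance"].sum()
    truth = truth.reindex(species_ids)

    # ranges cover exactly the occupied cells; area bookkeeping is exact
    range_area = density.groupby("species_id")["cell_area_km2"].sum().reindex(species_ids)

    # threat status tracks true rarity (rarer species -> higher category)
    rarity = -(np.log10(truth.to_numpy()))
    latent = (rarity - rarity.mean()) / rarity.std() + 0.6 * rng_tr.standard_normal(n)
    qs = np.quantile(latent, [0.50, 0.72, 0.86, 0.94, 0.985])
    iucn = np.searchsorted(qs, latent)

    traits = pd.DataFrame({
        "species_id": species_ids,
        "body_mass_g": body_mass_g,
        "flock_size": flock_size,
        "brightness": brightness,
        "dist_from_brown": dist_from_brown,
        "iucn_ordinal": iucn.astype(float),
    })

    taxonomy = _nested_taxonomy(n, rng_grp)
    # realm from the species' westernmost occupied column; guild random
    realm_of_col = np.array(REALMS)[
        (np.arange(grid.n_cols) * len(REALMS)) // grid.n_cols]
    first_col = np.array([min(range_cells[sp]) % grid.n_cols for sp in species_ids])
    grouping = pd.DataFrame({
        "species_id": species_ids,
        "genus": taxonomy["genus"],
        "family": taxonomy["family"],
        "order": taxonomy["order"],
        "realm": realm_of_col[first_col],
        "guild": rng_grp.choice(GUILDS, size=n),
    })

    tree = _yule_tree(species_ids, rng_tree)

    detect = pd.DataFrame({
        "species_id": species_ids,
        "detect_intercept": detect_intercept,
        "detect_slope": detect_slope,
    })

    return SyntheticWorld(
        config=config, species_ids=species_ids, grid=grid,
        true_log10_density=density[["species_id", "grid_id", "log10_density"]],
        detect=detect, traits=traits, grouping=grouping,
        range_cells=range_cells, range_area_km2=range_area,
        tree=tree, true_global_abundance=truth,
    )


def default_effort(world: SyntheticWorld, seed: int = 0) -> pd.DataFrame:
    """Spatially heterogeneous effort: checklists per (grid, month).

    Each cell gets a log-normal effort multiplier (SD ``effort_lognorm_sd``
    on the natural-log scale), emulating the strong geographic sampling
    bias of real citizen-science data.
    """
    cfg = world.config
    rng = as_rng(seed)
    mult = np.exp(rng.normal(0.0, cfg.effort_lognorm_sd, size=world.grid.n_cells))
    lam = cfg.checklists_per_month * mult
    rows = [(g, m, int(rng.poisson(lam[g])))
            for g in range(world.grid.n_cells) for m in range(1, 13)]
    return pd.DataFrame(rows, columns=["grid_id", "month", "n_checklists"])


def simulate_checklists(
    world: SyntheticWorld,
    effort: pd.DataFrame,
    seed: int = 0,
) -> ChecklistTable:
    """Simulate checklist events and per-species counts.

    Counts for species s in cell g are Poisson (or negative-binomial when
    ``config.overdispersion`` is set) with mean
    10^(b_s + m_s * log10 d_{s,g}).  A configurable fraction of events is
    incomplete, too short, too long, or travels too far, to exercise the
    quality filters downstream.
    """
    cfg = world.config
    if (effort["n_checklists"] < 0).any():
        raise ValueError("effort must be nonnegative")
    unknown = set(effort["grid_id"]) - set(range(world.grid.n_cells))
    if unknown:
        raise ValueError(f"effort references unknown grid cells: {sorted(unknown)[:5]}")
    rng_ev, rng_ct = spawn_rngs(seed, 2)

    eff = effort[effort["n_checklists"] > 0]
    n_total = int(eff["n_checklists"].sum())
    if n_total == 0:
        events = pd.DataFrame(columns=["checklist_id", "lat", "lon", "month",
                                       "duration_min", "distance_km", "complete"])
        counts = pd.DataFrame(columns=["checklist_id", "species_id", "count"])
        return ChecklistTable(events, counts)

    grid_ids = np.repeat(eff["grid_id"].to_numpy(), eff["n_checklists"].to_numpy())
    months = np.repeat(eff["month"].to_numpy(), eff["n_checklists"].to_numpy())
    lat_c, lon_c = world.grid.cell_center(grid_ids)
    half = world.grid.cell_deg / 2.0
    lat = lat_c + rng_ev.uniform(-half, half, n_total) * 0.999
    lon = lon_c + rng_ev.uniform(-half, half, n_total) * 0.999

    duration = rng_ev.uniform(10.0, 200.0, n_total)
    u = rng_ev.random(n_total)
    short = u < cfg.frac_short
    long_ = (u >= cfg.frac_short) & (u < cfg.frac_short + cfg.frac_long)
    duration[short] = rng_ev.uniform(0.5, 5.0, short.sum())
    duration[long_] = rng_ev.uniform(240.0, 400.0, long_.sum())
    distance = rng_ev.uniform(0.0, 4.5, n_total)
    far = rng_ev.random(n_total) < cfg.frac_far
    distance[far] = rng_ev.uniform(5.0, 15.0, far.sum())
    complete = rng_ev.random(n_total) >= cfg.frac_incomplete

    events = pd.DataFrame({
        "checklist_id": np.arange(n_total),
        "lat": lat, "lon": lon, "month": months,
        "duration_min": duration, "distance_km": distance,
        "complete": complete,
    })

    # per-species expected counts per cell
    det = world.detect.set_index("species_id")
    dens = world.true_log10_density
    lam = (det.loc[dens["species_id"], "detect_intercept"].to_numpy()
           + det.loc[dens["species_id"], "detect_slope"].to_numpy()
           * dens["log10_density"].to_numpy())
    lam = 10.0 ** lam
    lam_df = pd.DataFrame({"species_id": dens["species_id"],
                           "grid_id": dens["grid_id"], "lam": lam})

    ev_by_grid: dict[int, np.ndarray] = {}
    order = np.argsort(grid_ids, kind="stable")
    sorted_gids = grid_ids[order]
    bounds = np.searchsorted(sorted_gids, np.unique(sorted_gids))
    uniq = np.unique(sorted_gids)
    for i, g in enumerate(uniq):
        hi = bounds[i + 1] if i + 1 < len(uniq) else len(sorted_gids)
        ev_by_grid[g] = order[bounds[i]:hi]

    cl_rows, sp_rows, ct_rows = [], [], []
    for g, ev_idx in ev_by_grid.items():
        sub = lam_df[lam_df["grid_id"] == g]
        if sub.empty:
            continue
        lams = sub["lam"].to_numpy()
        if cfg.overdispersion is None:
            mat = rng_ct.poisson(lams[None, :], size=(ev_idx.size, lams.size))
        else:
            k = cfg.overdispersion
            gam = rng_ct.gamma(k, 1.0 / k, size=(ev_idx.size, lams.size))
            mat = rng_ct.poisson(lams[None, :] * gam)
        nz = np.nonzero(mat)
        cl_rows.append(ev_idx[nz[0]])
        sp_rows.append(sub["species_id"].to_numpy()[nz[1]])
        ct_rows.append(mat[nz])

    if cl_rows:
        counts = pd.DataFrame({
            "checklist_id": np.concatenate(cl_rows),
            "species_id": np.concatenate(sp_rows),
            "count": np.concatenate(ct_rows).astype(int),
        }).sort_values(["checklist_id", "species_id"]).reset_index(drop=True)
    else:
        counts = pd.DataFrame(columns=["checklist_id", "species_id", "count"])
    return ChecklistTable(events, counts)


def make_expert_estimates(
    world: SyntheticWorld,
    train_fraction: float = 0.3,
    noise_sd_log10: float = 0.5,
    mean_extra_regions: float = 1.0,
    seed: int = 0,
) -> ExpertEstimateTable:
    """Noisy regional truth for a training subsample of species.

    Each training species' occupied cells are partitioned into one or more
    regions (1 + Poisson(``mean_extra_regions``), capped at the cell
    count); the regional estimate is the exact regional abundance times
    10^Normal(0, noise_sd_log10).
    """
    if not (0 < train_fraction <= 1):
        raise ValueError("train_fraction must be in (0, 1]")
    if noise_sd_log10 < 0:
        raise ValueError("noise_sd_log10 must be >= 0")
    rng = as_rng(seed)
    n_train = max(1, round(train_fraction * len(world.species_ids)))
    train = sorted(rng.choice(world.species_ids, size=n_train, replace=False))

    dens = world.true_log10_density.set_index(["species_id", "grid_id"])
    rows, region_cells = [], {}
    for sp in train:
        cells = list(world.range_cells[sp])
        k = min(len(cells), 1 + int(rng.poisson(mean_extra_regions)))
        perm = rng.permutation(len(cells))
        chunks = np.array_split(perm, k)
        for j, chunk in enumerate(chunks):
            rcells = [cells[i] for i in chunk]
            region_id = f"{sp}_r{j}"
            area = float(world.grid.cell_area_km2(np.array(rcells)).sum())
            truth = float(sum(
                10 ** dens.loc[(sp, g), "log10_density"]
                * world.grid.cell_area_km2(np.array([g]))[0] for g in rcells))
            est = truth * 10 ** rng.normal(0.0, noise_sd_log10)
            rows.append((sp, region_id, est, area))
            region_cells[region_id] = rcells
    table = pd.DataFrame(rows, columns=["species_id", "region_id",
                                        "abundance_estimate", "region_area_km2"])
    return ExpertEstimateTable(table=table, region_cells=region_cells)


def apply_missingness(
    traits: pd.DataFrame,
    rates: dict[str, float],
    seed: int = 0,
    mechanism: str = "mcar",
) -> pd.DataFrame:
    """Blank out trait cells at the requested per-column rates.

    ``mcar`` masks completely at random; ``mar_flock`` makes missingness
    more likely for small-flock species (a stress test — real missingness
    mechanisms are unknown).
    """
    for col, r in rates.items():
        if not (0 <= r < 1):
            raise ValueError(f"missingness rate for {col} must be in [0, 1)")
        if col not in traits.columns:
            raise ValueError(f"unknown trait column {col!r}")
    rng = as_rng(seed)
    out = traits.copy()
    for col, r in rates.items():
        if r == 0:
            continue
        if mechanism == "mcar":
            mask = rng.random(len(out)) < r
        elif mechanism == "mar_flock":
            ranks = out["flock_size"].rank(pct=True).to_numpy()
            w = 1.0 - ranks  # small flocks more likely missing
            p = np.clip(r * w / w.mean(), 0, 0.999)
            mask = rng.random(len(out)) < p
        else:
            raise ValueError(f"unknown mechanism {mechanism!r}")
        out.loc[mask, col] = np.nan
    return out


def simulate_bm_trait(tree, sigma2: float, seed=None, mean: float = 0.0
                      ) -> pd.Series:
    """One Brownian-motion draw of a tip trait on the tree.

    Tip values are multivariate normal with covariance sigma2 times the
    shared-branch-length matrix.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    vcv = tree if isinstance(tree, PhyloVCV) else PhyloVCV.from_tree(tree)
    rng = as_rng(seed)
    L = np.linalg.cholesky(sigma2 * vcv.C + 1e-12 * np.eye(len(vcv.tips)))
    x = mean + L @ rng.standard_normal(len(vcv.tips))
    return pd.Series(x, index=vcv.tips)


def simulate_regression_data(
    n_species: int = 20,
    obs_per_species: int = 8,
    fixed_intercept: float = 0.0,
    fixed_slope: float = 1.0,
    sd_intercept: float = 0.3,
    sd_slope: float = 0.15,
    rho: float = -0.5,
    sigma_resid: float = 0.2,
    x_se: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw data straight from the measurement-error random-slope model.

    Returns (records, truth): records has one row per observation with
    ``species_id, log10_rel_abund, se_log10_rel_abund, log10_density``;
    truth has the per-species true intercept/slope.  Used for calibration
    and coverage checks of the regression fitter.
    """
    rng = as_rng(seed)
    cov = np.array([[sd_intercept**2, rho * sd_intercept * sd_slope],
                    [rho * sd_intercept * sd_slope, sd_slope**2]])
    re = rng.multivariate_normal([fixed_intercept, fixed_slope], cov, size=n_species)
    rows = []
    for s in range(n_species):
        b, m = re[s]
        x_true = rng.normal(0.0, 1.0, size=obs_per_species)
        x_obs = x_true + rng.normal(0.0, x_se, size=obs_per_species)
        y = b + m * x_true + rng.normal(0.0, sigma_resid, size=obs_per_species)
        for xo, yo in zip(x_obs, y):
            rows.append((f"sp{s:04d}", xo, x_se, yo))
    records = pd.DataFrame(rows, columns=[
        "species_id", "log10_rel_abund", "se_log10_rel_abund", "log10_density"])
    truth = pd.DataFrame({
        "species_id": [f"sp{s:04d}" for s in range(n_species)],
        "b": re[:, 0], "m": re[:, 1]})
    return records, truth


def write_world(world: SyntheticWorld, outdir) -> None:
    """Write the world's public files (CSV + newick) to a directory."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world.traits.to_csv(outdir / "traits.csv", index=False)
    world.grouping.to_csv(outdir / "groups.csv", index=False)
    rows = [(sp, g) for sp, cells in world.range_cells.items() for g in cells]
    pd.DataFrame(rows, columns=["species_id", "grid_id"]).to_csv(
        outdir / "ranges.csv", index=False)
    world.range_area_km2.rename("range_area_km2").rename_axis("species_id") \
        .reset_index().to_csv(outdir / "range_areas.csv", index=False)
    world.true_global_abundance.rename("true_global_abundance") \
        .rename_axis("species_id").reset_index().to_csv(
        outdir / "truth.csv", index=False)
    world.tree.write(path=str(outdir / "tree.nwk"), schema="newick")
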