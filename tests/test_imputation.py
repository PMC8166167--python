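"""Two-level chained PMM: assembly, donor matching, MI properties."""

import numpy as np
import pandas as pd
import pytest

import avabund as av
from avabund.imputation import (COMPLETE_COLUMNS, OBSERVATION_LEVEL,
                                SPECIES_LEVEL, marginal_r2,
                                missing_fractions, pmm_draw,
                                run_chained_imputation)


def small_table(n_species=30, grids_per_species=4, train_frac=0.4, seed=0,
                trait_missing=0.2):
    """Hand-built imputation table with known density relation."""
    rng = np.random.default_rng(seed)
    rows = []
    n_train = int(train_frac * n_species)
    for i in range(n_species):
        sp = f"s{i:03d}"
        mass = 10 ** rng.normal(1.5, 0.5)
        flock = 1 + rng.exponential(2)
        iucn = float(rng.integers(0, 5))
        brown = rng.normal(30, 10)
        bright = rng.normal(50, 15)
        base_density = rng.normal(-1, 1)
        for g in range(grids_per_species):
            d = base_density + rng.normal(0, 0.2)
            ra = 10 ** (0.7 - 0.3 * np.log10(mass) + d + rng.normal(0, 0.1))
            rows.append({
                "species_id": sp, "grid_id": g,
                "log_n_checklists": rng.normal(5, 1),
                "n_months_observed": float(rng.integers(1, 13)),
                "rel_abund": ra,
                "flock_size": flock, "iucn_ordinal": iucn,
                "body_mass": mass, "dist_from_brown": brown,
                "brightness": bright,
                "density_log10": d if i < n_train else np.nan,
                "density_se": 0.2 if i < n_train else np.nan,
            })
    tab = pd.DataFrame(rows)
    if trait_missing:
        for col in ("body_mass", "brightness"):
            sp_ids = tab["species_id"].unique()
            drop = rng.choice(sp_ids, size=int(trait_missing * len(sp_ids)),
                              replace=False)
            tab.loc[tab["species_id"].isin(drop), col] = np.nan
    return tab


class TestAssemble:
    def test_no_training_species_all_missing(self, tiny_result):
        tab = av.assemble_imputation_table(tiny_result.relabund,
                                           tiny_result.traits, None)
        assert tab["density_log10"].isna().all()
        assert tab["density_se"].isna().all()

    def test_density_and_se_missing_together(self, tiny_result):
        tab = tiny_result.imputation_table
        assert (tab["density_log10"].isna()
                == tab["density_se"].isna()).all()
        fr = missing_fractions(tab)
        # only training species rows carry densities
        assert 0 < fr["density_log10"] < 1

    def test_trait_missingness_passes_through(self, tiny_result):
        tab = tiny_result.imputation_table
        traits = tiny_result.traits.set_index("species_id")
        sp_na = set(traits.index[traits["brightness"].isna()])
        got_na = set(tab.loc[tab["brightness"].isna(), "species_id"])
        assert got_na == sp_na & set(tab["species_id"])

    def test_duplicate_rows_rejected(self, tiny_result):
        dup = pd.concat([tiny_result.relabund, tiny_result.relabund.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            av.assemble_imputation_table(dup, tiny_result.traits, None)


class TestPMMDraw:
    def test_no_missing_returns_unchanged(self):
        tab = small_table(train_frac=1.0, trait_missing=0)
        out = pmm_draw(tab, "density_se", ["rel_abund"], seed=0)
        pd.testing.assert_series_equal(out, tab["density_se"])

    def test_imputed_values_come_from_observed_set(self):
        tab = small_table()
        out = pmm_draw(tab, "density_log10",
                       ["rel_abund", "log_n_checklists"], seed=1)
        observed = set(tab["density_log10"].dropna())
        imputed = set(out[tab["density_log10"].isna()])
        assert imputed <= observed

    def test_species_level_one_value_per_species(self):
        tab = small_table()
        out = pmm_draw(tab, "body_mass",
                       ["rel_abund", "flock_size", "iucn_ordinal"],
                       level="species", seed=2)
        per_sp = pd.DataFrame({"species_id": tab["species_id"], "v": out})
        assert (per_sp.groupby("species_id")["v"].nunique() == 1).all()

    def test_nearest_donor_oracle_six_rows(self):
        """donors=1, no perturbation: exhaustive nearest-donor search."""
        tab = pd.DataFrame({
            "species_id": [f"s{i}" for i in range(6)],
            "x": [0.0, 1.0, 2.0, 3.0, 4.0, 2.4],
            "y": [0.1, 1.1, 2.3, 2.9, 4.2, np.nan],
        })
        out = pmm_draw(tab, "y", ["x"], donors=1, seed=0, perturb=False)
        # brute force: OLS fit on observed, predict, nearest predicted mean
        obs = tab.dropna()
        beta = np.polyfit(obs["x"], obs["y"], 1)
        pred_obs = np.polyval(beta, obs["x"])
        pred_mis = np.polyval(beta, 2.4)
        donor = obs["y"].to_numpy()[np.argmin(np.abs(pred_obs - pred_mis))]
        assert out.iloc[5] == donor

    def test_zero_observed_errors(self):
        tab = small_table(train_frac=0.0, trait_missing=0)
        with pytest.raises(ValueError, match="no observed"):
            pmm_draw(tab, "density_log10", ["rel_abund"], seed=0)

    def test_fewer_donors_than_requested_warns(self):
        tab = small_table(n_species=8, train_frac=0.25, trait_missing=0)
        with pytest.warns(UserWarning, match="donors"):
            pmm_draw(tab, "density_log10", ["rel_abund"], donors=50, seed=0)


class TestChained:
    def test_no_missing_gives_identical_copies(self):
        tab = small_table(train_frac=1.0, trait_missing=0)
        done = run_chained_imputation(tab, m=3, seed=0)
        for d in done.datasets:
            pd.testing.assert_frame_equal(d, tab)

    def test_observed_cells_immutable_and_range_preserved(self):
        tab = small_table()
        done = run_chained_imputation(tab, m=4, maxit=2, seed=3)
        for col in SPECIES_LEVEL + OBSERVATION_LEVEL:
            obs_mask = tab[col].notna()
            observed_vals = set(tab.loc[obs_mask, col])
            for d in done.datasets:
                assert d[col].notna().all()
                pd.testing.assert_series_equal(d.loc[obs_mask, col],
                                               tab.loc[obs_mask, col])
                assert set(d.loc[~obs_mask, col]) <= observed_vals

    def test_between_imputation_variance_positive(self):
        tab = small_table()
        done = run_chained_imputation(tab, m=5, maxit=2, seed=4)
        miss = tab["density_log10"].isna()
        stack = np.stack([d.loc[miss, "density_log10"].to_numpy()
                          for d in done.datasets])
        assert stack.var(axis=0).mean() > 0

    def test_seed_determinism(self):
        tab = small_table()
        a = run_chained_imputation(tab, m=3, maxit=2, seed=9)
        b = run_chained_imputation(tab, m=3, maxit=2, seed=9)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_m_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            run_chained_imputation(small_table(), m=1)

    def test_masking_oracle_marginal_r2(self):
        """Mask 30% of known densities; imputation recovers them (R2 >= 0.6)."""
        tab = small_table(n_species=60, grids_per_species=5, train_frac=1.0,
                          trait_missing=0.1, seed=5)
        rng = np.random.default_rng(6)
        mask = rng.random(len(tab)) < 0.3
        masked = tab.copy()
        masked.loc[mask, ["density_log10", "density_se"]] = np.nan
        done = run_chained_imputation(masked, m=5, maxit=3, seed=7)
        truth = tab.loc[mask, "density_log10"].to_numpy()
        imput = np.mean([d.loc[mask, "density_log10"].to_numpy()
                         for d in done.datasets], axis=0)
        codes = pd.Categorical(tab.loc[mask, "species_id"]).codes
        X = np.column_stack([np.ones(mask.sum()), truth])
        r2 = marginal_r2(imput, X, codes, codes.max() + 1)
        assert r2 >= 0.6

    def test_imputed_vs_observed_distribution_overlap(self):
        """KS distance between imputed and observed densities stays small."""
        from scipy.stats import ks_2samp
        tab = small_table(n_species=60, grids_per_species=5, seed=8)
        done = run_chained_imputation(tab, m=5, maxit=3, seed=9)
        miss = tab["density_log10"].isna()
        obs = tab.loc[~miss, "density_log10"].to_numpy()
        imp = np.concatenate([d.loc[miss, "density_log10"].to_numpy()
                              for d in done.datasets])
        assert ks_2samp(obs, imp).statistic < 0.25
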