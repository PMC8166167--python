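"""Generator correctness: determinism, bookkeeping, induced correlations."""

import numpy as np
import pandas as pd
import pytest

import avabund as av
from avabund.phylo import PhyloVCV
from avabund.synthetic import WorldConfig, _yule_tree


def test_empty_world_rejected():
    with pytest.raises(ValueError):
        av.generate_world(WorldConfig(n_species=0), seed=1)
    with pytest.raises(ValueError):
        av.generate_world(WorldConfig(n_grid_rows=0), seed=1)


def test_world_determinism():
    cfg = WorldConfig(n_species=25, n_grid_rows=3, n_grid_cols=3)
    w1 = av.generate_world(cfg, seed=5)
    w2 = av.generate_world(cfg, seed=5)
    pd.testing.assert_frame_equal(w1.true_log10_density, w2.true_log10_density)
    pd.testing.assert_frame_equal(w1.traits, w2.traits)
    pd.testing.assert_series_equal(w1.true_global_abundance,
                                   w2.true_global_abundance)
    assert w1.tree.as_string(schema="newick") == w2.tree.as_string(schema="newick")


def test_mass_intercept_correlation_sign_and_magnitude():
    """Body mass correlates negatively with the detection intercept (~-0.47)."""
    w = av.generate_world(WorldConfig(n_species=500), seed=1)
    r = np.corrcoef(np.log10(w.traits["body_mass_g"]),
                    w.detect["detect_intercept"])[0, 1]
    assert r < 0
    assert abs(r - (-0.467)) < 0.2


def test_ground_truth_bookkeeping(tiny_world):
    """Stored global abundance equals the sum of cell abundances exactly."""
    d = tiny_world.true_log10_density
    areas = tiny_world.grid.cell_area_km2(d["grid_id"].to_numpy())
    total = (10 ** d["log10_density"] * areas).groupby(d["species_id"]).sum()
    assert np.allclose(total.sort_index(),
                       tiny_world.true_global_abundance.sort_index(),
                       rtol=1e-12)
    for sp, cells in tiny_world.range_cells.items():
        assert set(cells) <= set(range(tiny_world.grid.n_cells))
    assert (tiny_world.range_area_km2 > 0).all()
    tips = {lf.taxon.label for lf in tiny_world.tree.leaf_node_iter()}
    assert tips == set(tiny_world.species_ids)


def test_checklist_count_mean_matches_detection_law():
    """Mean count per checklist converges to 10^(b + m log10 d)."""
    cfg = WorldConfig(n_species=2, n_grid_rows=1, n_grid_cols=1,
                      frac_incomplete=0, frac_short=0, frac_long=0, frac_far=0)
    w = av.generate_world(cfg, seed=3)
    # pin species 0: density 1/km^2, intercept log10(2), slope 1 -> E[count]=2
    w.true_log10_density.loc[:, "log10_density"] = 0.0
    w.detect.loc[0, ["detect_intercept", "detect_slope"]] = [np.log10(2.0), 1.0]
    effort = pd.DataFrame({"grid_id": [0], "month": [1], "n_checklists": [10000]})
    cl = av.simulate_checklists(w, effort, seed=4)
    sp = w.species_ids[0]
    total = cl.counts.loc[cl.counts["species_id"] == sp, "count"].sum()
    mean = total / 10000
    mc_se = np.sqrt(2.0 / 10000)  # Poisson
    assert abs(mean - 2.0) < 3 * mc_se


def test_zero_effort_gives_empty_table(tiny_world):
    effort = pd.DataFrame({"grid_id": [0], "month": [1], "n_checklists": [0]})
    cl = av.simulate_checklists(tiny_world, effort, seed=1)
    assert cl.n_events == 0 and len(cl.counts) == 0


def test_species_never_counted_outside_range(tiny_checklists, tiny_world):
    ev = tiny_checklists.events.copy()
    gid = tiny_world.grid.assign(ev["lat"].to_numpy(), ev["lon"].to_numpy())
    ev["grid_id"] = gid
    long = tiny_checklists.counts.merge(ev[["checklist_id", "grid_id"]],
                                        on="checklist_id")
    for sp, sub in long.groupby("species_id"):
        assert set(sub["grid_id"]) <= set(tiny_world.range_cells[sp])


def test_unknown_grid_effort_rejected(tiny_world):
    effort = pd.DataFrame({"grid_id": [999], "month": [1], "n_checklists": [5]})
    with pytest.raises(ValueError, match="unknown grid"):
        av.simulate_checklists(tiny_world, effort, seed=1)


class TestExpertEstimates:
    def test_zero_noise_exact(self, tiny_world):
        est = av.make_expert_estimates(tiny_world, train_fraction=1.0,
                                       noise_sd_log10=0.0, seed=2)
        assert set(est.table["species_id"]) == set(tiny_world.species_ids)
        per_sp = est.table.groupby("species_id")["abundance_estimate"].sum()
        assert np.allclose(per_sp.sort_index(),
                           tiny_world.true_global_abundance.sort_index(),
                           rtol=1e-9)

    def test_noise_sd_recovered(self):
        """SD of log10(estimate/truth) matches the requested noise SD."""
        w = av.generate_world(WorldConfig(n_species=500), seed=9)
        est = av.make_expert_estimates(w, train_fraction=1.0,
                                       noise_sd_log10=0.2, seed=10)
        truth = w.true_log10_density.set_index(["species_id", "grid_id"])
        areas_all = w.grid.cell_area_km2(np.arange(w.grid.n_cells))
        errs = []
        for r in est.table.itertuples():
            cells = est.region_cells[r.region_id]
            true_ab = sum(10 ** truth.loc[(r.species_id, g), "log10_density"]
                          * areas_all[g] for g in cells)
            errs.append(np.log10(r.abundance_estimate / true_ab))
        sd = np.std(errs, ddof=1)
        assert abs(sd - 0.2) < 0.02

    def test_invalid_params(self, tiny_world):
        with pytest.raises(ValueError):
            av.make_expert_estimates(tiny_world, train_fraction=0.0)
        with pytest.raises(ValueError):
            av.make_expert_estimates(tiny_world, noise_sd_log10=-0.1)


class TestMissingness:
    def test_zero_rates_unchanged(self, tiny_world):
        out = av.apply_missingness(tiny_world.traits, {"body_mass_g": 0.0},
                                   seed=1)
        pd.testing.assert_frame_equal(out, tiny_world.traits)

    def test_realized_fractions(self):
        n = 10000
        rng = np.random.default_rng(0)
        traits = pd.DataFrame({
            "species_id": [f"s{i}" for i in range(n)],
            "iucn_ordinal": rng.integers(0, 5, n).astype(float),
            "body_mass_g": rng.lognormal(3, 1, n),
            "dist_from_brown": rng.normal(30, 10, n),
            "flock_size": 1 + rng.exponential(2, n),
        })
        rates = {"iucn_ordinal": 0.08, "body_mass_g": 0.16,
                 "dist_from_brown": 0.40}
        out = av.apply_missingness(traits, rates, seed=0)
        for col, r in rates.items():
            realized = out[col].isna().mean()
            tol = 3 * np.sqrt(r * (1 - r) / n)
            assert abs(realized - r) < tol, col

    def test_seed_determinism_and_bad_rate(self, tiny_world):
        a = av.apply_missingness(tiny_world.traits, {"brightness": 0.3}, seed=4)
        b = av.apply_missingness(tiny_world.traits, {"brightness": 0.3}, seed=4)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            av.apply_missingness(tiny_world.traits, {"brightness": 1.0})


class TestBrownianTrait:
    def test_two_tip_variance(self):
        import dendropy
        tree = dendropy.Tree.get(data="(a:2,b:2);", schema="newick")
        vcv = PhyloVCV.from_tree(tree)
        diffs = [av.simulate_bm_trait(vcv, 1.0, seed=i) for i in range(800)]
        d = np.array([t["a"] - t["b"] for t in diffs])
        # Var(x_a - x_b) = 2t = 4; SE of sample var ~ var*sqrt(2/n)
        assert abs(d.var(ddof=1) - 4.0) < 4.0 * 3 * np.sqrt(2 / 800)

    def test_tip_covariance_matches_brute_force_vcv(self):
        """PhyloVCV equals shared path lengths from node-distance arithmetic."""
        rng = np.random.default_rng(7)
        tree = _yule_tree([f"t{i}" for i in range(20)], rng)
        vcv = PhyloVCV.from_tree(tree)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        root_dist = {lf.taxon.label: lf.distance_from_root()
                     for lf in tree.leaf_node_iter()}
        stem = tree.seed_node.edge.length or 0.0
        for i, a in enumerate(vcv.tips):
            for j, b in enumerate(vcv.tips):
                if i == j:
                    expect = root_dist[a] - stem
                else:
                    expect = 0.5 * (root_dist[a] + root_dist[b]
                                    - pdm.patristic_distance(taxa[a], taxa[b])) \
                        - stem
                assert vcv.C[i, j] == pytest.approx(expect, abs=1e-7)

    def test_bad_sigma2(self, star_tree):
        with pytest.raises(ValueError):
            av.simulate_bm_trait(star_tree, 0.0)
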