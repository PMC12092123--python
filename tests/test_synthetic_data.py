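import statistics

import numpy as np
import pytest

import venomphylo as vp
from venomphylo.data_io import read_table
from venomphylo.diet_scoring import reports_to_profiles
from venomphylo.errors import DomainError
from venomphylo.synthetic_data import (
    GroundTruth,
    make_dataset,
    prey_class_map,
    simulate_diets,
    simulate_traits,
    write_dataset,
)


class TestTree:
    def test_two_tips_is_cherry_at_root_depth(self):
        tree = vp.simulate_tree(2, 0, root_depth=300.0)
        assert tree.n_tips == 2
        assert tree.depth == pytest.approx(300.0)

    def test_default_shape_is_ultrametric(self):
        tree = vp.simulate_tree(75, 12)
        assert tree.n_tips == 75
        assert tree.is_ultrametric(rel_tol=1e-9)
        assert tree.depth == pytest.approx(300.0)

    def test_same_seed_same_newick(self):
        assert vp.simulate_tree(40, 5).to_newick() == (
            vp.simulate_tree(40, 5).to_newick()
        )

    def test_single_tip_rejected(self):
        with pytest.raises(DomainError):
            vp.simulate_tree(1, 0)


class TestDiets:
    def test_profiles_are_valid(self):
        diets = simulate_diets([f"s{i}" for i in range(30)], seed=1)
        for profile in diets.values():
            assert sum(profile.weights.values()) == pytest.approx(1.0)
            assert all(w > 0 for w in profile.weights.values())

    def test_median_class_richness_is_four(self):
        diets = simulate_diets([f"s{i}" for i in range(200)], seed=77)
        cmap = prey_class_map()
        richness = [
            vp.diet_class_richness(p, cmap) for p in diets.values()
        ]
        assert statistics.median(richness) == 4

    def test_large_concentration_gives_near_uniform_weights(self):
        diets = simulate_diets(["sp"], concentration=1e6, seed=3,
                               mean_extra_taxa=8.0)
        w = list(diets["sp"].weights.values())
        assert max(w) - min(w) < 0.01

    def test_single_prey_taxon_gets_weight_one(self):
        diets = simulate_diets(["sp"], prey_taxa=["Insecta"], seed=0)
        assert diets["sp"].weights == {"Insecta": pytest.approx(1.0)}


class TestLD50:
    def test_noiseless_generation_recovered_by_ols(self):
        gt = GroundTruth(sigma2_animal=0.0, sigma2_species=0.0,
                         sigma2_resid=0.0, beta_d=0.4, beta_mass=0.1,
                         beta_silk=0.2)
        tree = vp.simulate_tree(40, 2)
        species = tree.tip_labels
        silk = vp.simulate_binary_trait(tree, 0.004, 3)
        traits = simulate_traits(species, 4, silk_states=silk)
        diets = simulate_diets(species, seed=5)
        sim = vp.simulate_ld50(tree, diets, traits, gt, 6)
        df = sim.table
        route_cols = []
        for r in ("IV", "SC", "abdomen", "thorax_cephalothorax"):
            route_cols.append((df["route"] == r).to_numpy(float))
        x = np.column_stack(
            [np.ones(len(df)), df["d_ld50_diet"], df["log10_mass"],
             df["silk_use"]] + route_cols
        )
        coef, *_ = np.linalg.lstsq(x, df["log10_ld50"].to_numpy(),
                                   rcond=None)
        assert coef[1] == pytest.approx(0.4, abs=1e-6)
        assert coef[2] == pytest.approx(0.1, abs=1e-6)
        assert coef[3] == pytest.approx(0.2, abs=1e-6)

    def test_same_seed_identical_records(self):
        tree = vp.simulate_tree(20, 2)
        species = tree.tip_labels
        traits = simulate_traits(species, 4)
        diets = simulate_diets(species, seed=5)
        a = vp.simulate_ld50(tree, diets, traits, GroundTruth(), 6)
        b = vp.simulate_ld50(tree, diets, traits, GroundTruth(), 6)
        assert a.table.equals(b.table)

    def test_routes_match_model_organism(self):
        ds = make_dataset(n_species=30, seed=9, n_assay_species=25)
        vert = ds.assays["model_organism"] == "Mus musculus"
        assert set(ds.assays.loc[vert, "route"]) <= {"IP", "IV", "SC"}
        assert set(ds.assays.loc[~vert, "route"]) <= {
            "thorax_cephalothorax", "abdomen"
        }


class TestYield:
    def test_noiseless_slope_exact(self):
        traits = simulate_traits([f"s{i}" for i in range(30)], 1)
        y = vp.simulate_yield(traits, noise_sd=0.0, seed=2)
        fit = vp.fit_loglog_slope(y["body_mass_g"], y["venom_yield_mg"])
        assert fit.exponent == pytest.approx(0.75, abs=1e-10)

    def test_sampling_distribution_of_slope(self):
        traits = simulate_traits([f"s{i}" for i in range(60)], 1)
        inside = 0
        for rep in range(200):
            y = vp.simulate_yield(traits, seed=3000 + rep)
            fit = vp.fit_loglog_slope(y["body_mass_g"],
                                      y["venom_yield_mg"])
            inside += 0.5 < fit.exponent < 1.0
        assert inside / 200 >= 0.95


class TestBinaryTrait:
    def test_zero_rate_keeps_root_state(self):
        tree = vp.simulate_tree(30, 3)
        states = vp.simulate_binary_trait(tree, 0.0, 4)
        assert len(set(states.values())) == 1

    def test_high_rate_reaches_equilibrium(self):
        freq = []
        for s in range(50):
            tree = vp.simulate_tree(100, 500 + s)
            states = vp.simulate_binary_trait(tree, 5.0, 600 + s)
            freq.append(np.mean(list(states.values())))
        assert 0.4 <= np.mean(freq) <= 0.6

    def test_same_seed_same_states(self):
        tree = vp.simulate_tree(30, 3)
        assert vp.simulate_binary_trait(tree, 0.01, 9) == (
            vp.simulate_binary_trait(tree, 0.01, 9)
        )


class TestDatasets:
    def test_default_shape_targets(self):
        ds = make_dataset(seed=3)
        assert ds.tree.n_tips == 75
        assert ds.assays["species"].nunique() == 64
        assert len(ds.yields) == 60
        assert ds.yields["species"].nunique() == 47

    def test_written_files_pass_schema_validation(self, tmp_path):
        ds = make_dataset(n_species=20, seed=5, n_assay_species=15,
                          n_yield_species=10, n_yield_measures=14)
        write_dataset(ds, tmp_path)
        assays = read_table(tmp_path / "assays.csv", "assays")
        assert len(assays) == len(ds.assays)
        traits = read_table(tmp_path / "traits.csv", "traits")
        assert len(traits) == 20
        rows = read_table(tmp_path / "diet_reports.csv", "diet_reports")
        profiles = reports_to_profiles(rows)
        assert set(profiles) == set(ds.diets)
        for sp, profile in profiles.items():
            assert profile.weights == pytest.approx(ds.diets[sp].weights)
        cmap = read_table(tmp_path / "class_map.csv", "taxon_class_map")
        assert cmap == prey_class_map()
        tree = vp.read_newick(tmp_path / "tree.newick")
        assert tree.to_newick() == ds.tree.to_newick()

    def test_regeneration_is_byte_identical(self, tmp_path):
        for d in ("one", "two"):
            write_dataset(make_dataset(n_species=15, seed=11,
                                       n_assay_species=12,
                                       n_yield_species=8,
                                       n_yield_measures=10),
                          tmp_path / d)
        files = sorted(p.name for p in (tmp_path / "one").iterdir())
        assert files
        for name in files:
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()

    def test_end_to_end_sign_recovery(self):
        # generate -> distance -> fit: nonzero effects keep their sign
        ds = make_dataset(n_species=40, seed=21, n_assay_species=36)
        spec = vp.ModelSpec(
            response="log10_ld50",
            continuous=["d_ld50_diet", "log10_mass", "silk_use"],
            categorical={"route": "IP"},
            chains=vp.ChainSettings(iterations=6000, burnin=1500, thin=5,
                                    n_chains=1, seed=2),
        )
        summ = vp.summarize(vp.fit_pmm(ds.assays, spec, ds.tree))
        fe = summ.fixed_effects
        assert fe.loc["d_ld50_diet", "mean"] > 0
        assert fe.loc["route[thorax_cephalothorax]", "mean"] > 0
        assert fe.loc["route[abdomen]", "mean"] > 0
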