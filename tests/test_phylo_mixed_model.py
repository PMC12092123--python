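import numpy as np
import pandas as pd
import pytest

import venomphylo as vp
from venomphylo.errors import (
    DomainError,
    InsufficientDataError,
    RankDeficiencyError,
)
from venomphylo.phylo_mixed_model import (
    ChainSettings,
    ModelSpec,
    PosteriorDraws,
    build_design,
)
from venomphylo.synthetic_data import simulate_tree


def quick_chains(**kw):
    defaults = dict(iterations=4000, burnin=1000, thin=3, n_chains=1,
                    seed=123)
    defaults.update(kw)
    return ChainSettings(**defaults)


class TestCorrelationMatrix:
    def test_toy_tree_shared_depth(self, toy_tree):
        a = vp.phylo_correlation_matrix(toy_tree, ["A", "B", "C"])
        assert a[0, 0] == a[1, 1] == a[2, 2] == 1.0
        assert a[0, 1] == pytest.approx(200 / 300)
        assert a[0, 2] == pytest.approx(0.0)
        assert np.allclose(a, a.T)

    def test_star_tree_gives_identity(self):
        star = vp.read_newick("(A:1,B:1,C:1,D:1);")
        a = vp.phylo_correlation_matrix(star, ["A", "B", "C", "D"])
        assert np.allclose(a, np.eye(4))

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_patristic_based_oracle(self, seed):
        # independent route: shared depth = total depth - patristic/2
        tree = simulate_tree(15, seed)
        species = tree.tip_labels
        a = vp.phylo_correlation_matrix(tree, species)
        pdm = tree.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.tree.taxon_namespace}
        depth = tree.depth
        for i, si in enumerate(species):
            for j, sj in enumerate(species):
                if i == j:
                    continue
                patristic = pdm.patristic_distance(taxa[si], taxa[sj])
                assert a[i, j] == pytest.approx(
                    (depth - patristic / 2) / depth, abs=1e-8
                )

    def test_positive_semidefinite(self):
        tree = simulate_tree(25, 9)
        a = vp.phylo_correlation_matrix(tree, tree.tip_labels)
        assert np.linalg.eigvalsh(a).min() > -1e-10


class TestDesign:
    def test_categorical_uses_reference_level(self):
        df = pd.DataFrame({
            "y": [1.0, 2.0, 3.0],
            "route": ["IP", "SC", "IV"],
        })
        spec = ModelSpec(response="y", categorical={"route": "IP"},
                         random_terms=(), chains=quick_chains())
        x, names = build_design(df, spec)
        assert names == ["(Intercept)", "route[IV]", "route[SC]"]
        assert x[:, 1].tolist() == [0.0, 0.0, 1.0]

    def test_collinear_columns_named(self):
        df = pd.DataFrame({
            "y": [1.0, 2.0, 3.0, 4.0],
            "x1": [1.0, 2.0, 3.0, 4.0],
            "x2": [2.0, 4.0, 6.0, 8.0],
        })
        spec = ModelSpec(response="y", continuous=["x1", "x2"],
                         random_terms=(), chains=quick_chains())
        with pytest.raises(RankDeficiencyError) as err:
            build_design(df, spec)
        assert set(err.value.columns) & {"x1", "x2"}


class TestGibbsSampler:
    def test_intercept_only_matches_sample_mean(self, rng):
        y = rng.normal(3.0, 1.0, size=40)
        df = pd.DataFrame({"y": y})
        spec = ModelSpec(response="y", random_terms=(),
                         chains=quick_chains(iterations=6000, burnin=1000))
        draws = vp.fit_pmm(df, spec)
        summ = vp.summarize(draws)
        flat = draws.fixed[:, :, 0].ravel()
        mcse = flat.std() / np.sqrt(summ.ess["(Intercept)"])
        assert abs(flat.mean() - y.mean()) < 3 * mcse + 1e-6

    def test_null_animal_variance_recovers_small_h2(self):
        # data with no phylogenetic component: h2 should be near zero
        tree = simulate_tree(60, 7)
        species = tree.tip_labels
        rng = np.random.default_rng(3)
        sp_col = [s for s in species for _ in range(2)]
        idx = np.repeat(np.arange(60), 2)
        x1 = rng.normal(size=120)
        s_eff = 0.3 * rng.standard_normal(60)
        y = 0.5 + 0.4 * x1 + s_eff[idx] + 0.5 * rng.standard_normal(120)
        df = pd.DataFrame({"species": sp_col, "x1": x1, "y": y})
        spec = ModelSpec(
            response="y", continuous=["x1"],
            chains=quick_chains(iterations=10000, burnin=2000, thin=8,
                                seed=2),
        )
        summ = vp.summarize(vp.fit_pmm(df, spec, tree))
        assert summ.h2_mean < 0.1

    def test_seeded_draw_stream_is_reproducible(self):
        tree = simulate_tree(10, 1)
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "species": tree.tip_labels,
            "x": rng.normal(size=10),
            "y": rng.normal(size=10),
        })
        spec = ModelSpec(response="y", continuous=["x"],
                         chains=quick_chains(iterations=600, burnin=100,
                                             thin=1, n_chains=2))
        a = vp.fit_pmm(df, spec, tree)
        b = vp.fit_pmm(df, spec, tree)
        assert np.array_equal(a.fixed, b.fixed)
        for k in a.sigma2:
            assert np.array_equal(a.sigma2[k], b.sigma2[k])

    def test_h2_invariant_to_response_scaling(self):
        tree = simulate_tree(30, 4)
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "species": tree.tip_labels,
            "y": rng.normal(size=30),
        })
        chains = quick_chains(iterations=8000, burnin=2000, thin=6)
        spec = ModelSpec(response="y", chains=chains)
        h2_base = vp.summarize(vp.fit_pmm(df, spec, tree)).h2_mean
        df2 = df.assign(y=df["y"] * 10.0)
        spec2 = ModelSpec(response="y", chains=chains)
        h2_scaled = vp.summarize(vp.fit_pmm(df2, spec2, tree)).h2_mean
        assert h2_scaled == pytest.approx(h2_base, abs=0.05)

    def test_posterior_mean_approaches_gls_with_chain_length(self):
        """With variances pinned, the Monte-Carlo error of the posterior
        mean of the fixed effects against the closed-form GLS estimate
        shrinks as chains grow (averaged over seeds to suppress noise)."""
        from venomphylo.phylo_mixed_model import (
            VariancePrior,
            phylo_correlation_matrix,
        )

        rng = np.random.default_rng(14)
        tree = simulate_tree(15, 8)
        species = tree.tip_labels
        a_mat = phylo_correlation_matrix(tree, species)
        reps = rng.integers(1, 4, size=15)
        sp_col = [s for s, r in zip(species, reps) for _ in range(r)]
        n = len(sp_col)
        idx = np.array([species.index(s) for s in sp_col])
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        s2a, s2s, s2e = 0.3, 0.2, 0.4
        la = np.linalg.cholesky(a_mat + 1e-10 * np.eye(15))
        y = (
            x @ np.array([1.0, 0.5])
            + (np.sqrt(s2a) * (la @ rng.standard_normal(15)))[idx]
            + (np.sqrt(s2s) * rng.standard_normal(15))[idx]
            + np.sqrt(s2e) * rng.standard_normal(n)
        )
        z = np.zeros((n, 15))
        z[np.arange(n), idx] = 1.0
        v = s2a * z @ a_mat @ z.T + s2s * z @ z.T + s2e * np.eye(n)
        vi = np.linalg.inv(v)
        gls = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
        df = pd.DataFrame({"species": sp_col, "x1": x[:, 1], "y": y})

        errors = []
        for iters in (500, 3000, 20000):
            per_seed = []
            for seed in range(50, 54):
                spec = ModelSpec(
                    response="y", continuous=["x1"],
                    priors={
                        "animal": VariancePrior.strong(s2a),
                        "species": VariancePrior.strong(s2s),
                        "residual": VariancePrior.strong(s2e),
                    },
                    chains=ChainSettings(iterations=iters, burnin=100,
                                         thin=1, n_chains=1, seed=seed),
                )
                draws = vp.fit_pmm(df, spec, tree)
                per_seed.append(
                    float(np.max(np.abs(draws.fixed[0].mean(0) - gls)))
                )
            errors.append(float(np.mean(per_seed)))
        assert errors[0] > errors[1] > errors[2]

    def test_animal_term_requires_tree(self):
        df = pd.DataFrame({"species": ["a", "b"], "y": [1.0, 2.0]})
        spec = ModelSpec(response="y", chains=quick_chains())
        with pytest.raises(DomainError):
            vp.fit_pmm(df, spec, tree=None)


def make_draws(sig_a, sig_s, sig_e, beta=None):
    """Assemble a PosteriorDraws object from explicit per-draw values."""
    n = len(sig_a)
    beta = np.zeros(n) if beta is None else np.asarray(beta, float)
    spec = ModelSpec(response="y", random_terms=("animal", "species"),
                     chains=quick_chains())
    return PosteriorDraws(
        fixed_names=["(Intercept)"],
        fixed=beta.reshape(1, n, 1),
        sigma2={
            "animal": np.asarray(sig_a, float).reshape(1, n),
            "species": np.asarray(sig_s, float).reshape(1, n),
            "residual": np.asarray(sig_e, float).reshape(1, n),
        },
        animal=None,
        species_effect=None,
        species_order=[],
        spec=spec,
    )


class TestSummarize:
    def test_equal_components_give_h2_one_third(self):
        v = np.full(50, 0.7)
        summ = vp.summarize(make_draws(v, v, v))
        assert summ.h2_mean == pytest.approx(1 / 3, abs=1e-12)
        assert summ.h2_lower == pytest.approx(1 / 3)
        assert summ.h2_upper == pytest.approx(1 / 3)

    def test_all_positive_draws_significant(self):
        v = np.full(50, 1.0)
        beta = np.linspace(0.5, 1.5, 50)
        summ = vp.summarize(make_draws(v, v, v, beta=beta))
        assert summ.significant("(Intercept)")

    def test_symmetric_draws_not_significant(self):
        v = np.full(50, 1.0)
        beta = np.concatenate([np.linspace(-1, -0.1, 25),
                               np.linspace(0.1, 1, 25)])
        summ = vp.summarize(make_draws(v, v, v, beta=beta))
        assert not summ.significant("(Intercept)")

    def test_h2_denominator_option(self):
        sa = np.full(20, 2.0)
        ss = np.full(20, 1.0)
        se = np.full(20, 1.0)
        d = make_draws(sa, ss, se)
        assert vp.summarize(d).h2_mean == pytest.approx(0.5)
        assert vp.summarize(
            d, h2_denominator="animal_residual"
        ).h2_mean == pytest.approx(2 / 3)

    def test_too_few_draws_rejected(self):
        with pytest.raises(InsufficientDataError):
            vp.summarize(make_draws([1.0], [1.0], [1.0]))


class TestGelmanRubin:
    def test_identical_chains_near_one(self, rng):
        stream = rng.normal(size=200)
        rhat = vp.gelman_rubin([stream, stream, stream])
        assert rhat <= 1.01

    def test_divergent_chains_flagged(self, rng):
        a = rng.normal(0.0, 0.01, size=100)
        b = rng.normal(100.0, 0.01, size=100)
        assert vp.gelman_rubin([a, b]) > 1.1

    def test_matches_hand_formula_on_toy_chains(self):
        c1 = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        c2 = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]
        # hand evaluation with plain python arithmetic
        n = 10
        m1, m2 = sum(c1) / n, sum(c2) / n
        v1 = sum((x - m1) ** 2 for x in c1) / (n - 1)
        v2 = sum((x - m2) ** 2 for x in c2) / (n - 1)
        w = (v1 + v2) / 2
        grand = (m1 + m2) / 2
        b = n * ((m1 - grand) ** 2 + (m2 - grand) ** 2) / (2 - 1)
        expected = ((n - 1) / n * w + b / n) / w
        assert vp.gelman_rubin([c1, c2]) == pytest.approx(
            expected ** 0.5, abs=1e-12
        )

    def test_single_chain_rejected(self):
        with pytest.raises(DomainError):
            vp.gelman_rubin([[1.0] * 20])
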