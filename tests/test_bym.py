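"""Sampler correctness against independent oracles.

The two central checks integrate the exact posterior by brute force —
1-D quadrature for the intercept-only model and a 3-D grid for a
three-district toy — and require the Gibbs sampler to reproduce them.
Neither oracle shares any code with the sampler.
"""

import numpy as np
import pytest
from scipy.special import expit

import districtprev as dp
from districtprev import bym, geo
from districtprev.synthetic import ClusterSite, SurveyDataset, WomanRecord


def intercept_design(y, district_ids=None):
    n = len(y)
    dist = np.array(district_ids if district_ids is not None else ["d1"] * n, dtype=object)
    return bym.DesignMatrix(
        y=np.asarray(y, dtype=float), X=np.ones((n, 1)), columns=["intercept"], district_ids=dist
    )


class TestICARQuadform:
    def test_zero_vector(self, lattice_3x3):
        adj = geo.build_adjacency(lattice_3x3)
        assert dp.icar_quadform(np.zeros(9), adj, 3.0) == 0.0

    def test_two_node_closed_form(self):
        adj = geo.AdjacencyGraph(nodes=["a", "b"], edges={("a", "b")})
        assert dp.icar_quadform(np.array([1.0, -1.0]), adj, 1.0) == pytest.approx(-2.0)

    def test_translation_invariance(self, lattice_3x3, rng):
        adj = geo.build_adjacency(lattice_3x3)
        f = rng.standard_normal(9)
        assert dp.icar_quadform(f, adj, 2.0) == pytest.approx(dp.icar_quadform(f + 5.7, adj, 2.0))

    def test_dimension_mismatch(self, lattice_3x3):
        adj = geo.build_adjacency(lattice_3x3)
        with pytest.raises(ValueError):
            dp.icar_quadform(np.zeros(4), adj, 1.0)


class TestBuildDesign:
    @staticmethod
    def two_women():
        clusters = [ClusterSite("c1", 0, 0, True, 0, 0), ClusterSite("c2", 0, 0, False, 0, 0)]
        records = [
            WomanRecord("w1", "c1", 25, 17, True, "secondary", 3, 1.0),
            WomanRecord("w2", "c2", 24, None, False, "none", 1, 1.0),
        ]
        return SurveyDataset(records=records, clusters=clusters)

    def test_dummy_coding(self):
        ds = self.two_women()
        spec = bym.ModelSpec(bracket="16to17", sampler=bym.SamplerSettings(seed=1))
        design = bym.build_design(ds, spec, {"c1": "dA", "c2": "dB"})
        row = dict(zip(design.columns, design.X[0]))
        assert row["intercept"] == 1 and row["urban"] == 1
        assert row["education:secondary"] == 1 and row["wealth:3"] == 1
        assert sum(design.X[0]) == 4  # nothing else set
        # all-reference woman: intercept only
        assert sum(design.X[1]) == 1
        np.testing.assert_array_equal(design.y, [1.0, 0.0])

    def test_unassigned_cluster_error(self):
        ds = self.two_women()
        spec = bym.ModelSpec(sampler=bym.SamplerSettings(seed=1))
        with pytest.raises(bym.SchemaError, match="c2"):
            bym.build_design(ds, spec, {"c1": "dA"})

    def test_collinear_column_rejected(self):
        X = np.ones((10, 2))  # duplicate intercept
        with pytest.raises(ValueError, match="rank"):
            bym.DesignMatrix(y=np.zeros(10), X=X, columns=["intercept", "dup"],
                             district_ids=np.array(["d"] * 10, dtype=object))

    def test_exclusion_flag_drops_earlier_births(self):
        ds = self.two_women()
        spec = bym.ModelSpec(bracket="18to19", exclude_earlier_births=True,
                             sampler=bym.SamplerSettings(seed=1))
        design = bym.build_design(ds, spec, {"c1": "dA", "c2": "dB"})
        assert len(design.y) == 1  # woman with birth at 17 excluded


class TestPosteriorSummary:
    def test_constant_draws(self):
        s = dp.posterior_summary(np.full(500, 0.3))
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.ci_width == pytest.approx(0.0, abs=1e-12)
        assert s.mean == pytest.approx(0.3)

    def test_normal_quantile_sequence_width(self):
        from scipy.stats import norm

        draws = norm.ppf((np.arange(10_000) + 0.5) / 10_000)
        s = dp.posterior_summary(draws)
        assert s.ci_width == pytest.approx(2 * 1.959964, abs=0.01)
        assert s.mean == pytest.approx(0.0, abs=1e-10)

    def test_few_draws_warns(self):
        with pytest.warns(UserWarning, match="draws"):
            dp.posterior_summary(np.arange(50.0))


class TestQuadratureOracle:
    def test_intercept_only_matches_1d_quadrature(self):
        """Posterior mean of logistic(beta0) for 30 successes of 100 under a
        Normal(0, 10^2) prior, against direct numerical integration."""
        y = np.zeros(100)
        y[:30] = 1.0
        design = intercept_design(y)
        adj = geo.AdjacencyGraph(nodes=["d1"], edges=set())
        spec = bym.ModelSpec(
            spatial="none", prior_beta_sd=10.0,
            sampler=bym.SamplerSettings(n_iter=6000, n_burnin=1000, n_thin=1, seed=31),
        )
        fit = bym.fit_model(spec, design, adj)
        mcmc_mean = expit(fit.beta[:, 0]).mean()

        b = np.linspace(-8, 8, 20_001)
        logpost = 30 * b - 100 * np.logaddexp(0, b) - 0.5 * (b / 10.0) ** 2
        w = np.exp(logpost - logpost.max())
        oracle = np.trapezoid(expit(b) * w, b) / np.trapezoid(w, b)
        assert mcmc_mean == pytest.approx(oracle, abs=0.02)


class TestGridOracle:
    def test_three_district_toy_matches_grid_posterior(self):
        """BYM district probabilities on a 3-district path graph with 12
        observations, against a brute-force 3-D grid posterior.

        With fixed precisions the prior of eta_j = beta0 + u_j + v_j is the
        3-D Gaussian sigma_b^2*11' + pinv(Q)/tau_s + I/tau_v, and the
        likelihood depends on eta alone, so the full posterior reduces to
        three dimensions and can be integrated on a grid.
        """
        nodes = ["d1", "d2", "d3"]
        adj = geo.AdjacencyGraph(nodes=nodes, edges={("d1", "d2"), ("d2", "d3")})
        counts = {"d1": (3, 4), "d2": (1, 4), "d3": (2, 4)}  # successes, trials
        y, dist = [], []
        for d, (s, n) in counts.items():
            y += [1.0] * s + [0.0] * (n - s)
            dist += [d] * n
        design = intercept_design(y, dist)
        tau_s, tau_v, sd_b = 1.0, 1.0, 1.0
        spec = bym.ModelSpec(
            spatial="bym", prior_beta_sd=sd_b, tau_fixed=(tau_s, tau_v),
            sampler=bym.SamplerSettings(n_iter=22_000, n_burnin=2000, n_thin=2, seed=8),
        )
        fit = bym.fit_model(spec, design, adj)
        eta_draws = fit.beta[:, [0]] + fit.f_spat()
        mcmc_p = expit(eta_draws).mean(axis=0)

        q = adj.laplacian()
        sigma = sd_b**2 * np.ones((3, 3)) + np.linalg.pinv(q, hermitian=True, rcond=1e-8) / tau_s + np.eye(3) / tau_v
        prec = np.linalg.inv(sigma)
        g = np.linspace(-5.0, 5.0, 81)
        e1, e2, e3 = np.meshgrid(g, g, g, indexing="ij")
        eta = np.stack([e1, e2, e3], axis=-1)
        logprior = -0.5 * np.einsum("...i,ij,...j->...", eta, prec, eta)
        loglik = np.zeros_like(logprior)
        for j, d in enumerate(nodes):
            s, n = counts[d]
            loglik += s * eta[..., j] - n * np.logaddexp(0, eta[..., j])
        w = np.exp(logprior + loglik - (logprior + loglik).max())
        z = w.sum()
        oracle_p = np.array([(expit(eta[..., j]) * w).sum() / z for j in range(3)])

        np.testing.assert_allclose(mcmc_p, oracle_p, atol=0.03)


class TestSamplerBehaviour:
    def test_seed_reproducibility(self, small_survey):
        _, _, adj, ds = small_survey
        assignment = dict(ds.truth.cluster_district)
        spec = bym.ModelSpec(sampler=bym.SamplerSettings(n_iter=400, n_burnin=100, n_thin=1, seed=5))
        design = bym.build_design(ds, spec, assignment)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = bym.fit_model(spec, design, adj)
            f2 = bym.fit_model(spec, design, adj)
        np.testing.assert_array_equal(f1.beta, f2.beta)
        np.testing.assert_array_equal(f1.f_struc, f2.f_struc)
        np.testing.assert_array_equal(f1.tau_unstruc, f2.tau_unstruc)

    def test_sum_to_zero_every_draw(self, small_survey):
        _, _, adj, ds = small_survey
        assignment = dict(ds.truth.cluster_district)
        spec = bym.ModelSpec(sampler=bym.SamplerSettings(n_iter=600, n_burnin=200, n_thin=1, seed=3))
        design = bym.build_design(ds, spec, assignment)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = bym.fit_model(spec, design, adj)
        assert np.abs(fit.f_struc.sum(axis=1)).max() < 1e-8

    def test_besag_equals_bym_with_pinned_unstructured(self, small_survey):
        """Forcing tau_unstruc to a huge constant pins the iid effects near
        zero, so the BYM beta posterior must agree with plain Besag."""
        _, _, adj, ds = small_survey
        assignment = dict(ds.truth.cluster_district)
        settings = bym.SamplerSettings(n_iter=4000, n_burnin=1000, n_thin=1, seed=19)
        spec_b = bym.ModelSpec(spatial="besag", sampler=settings)
        design = bym.build_design(ds, spec_b, assignment)
        fit_b = bym.fit_model(spec_b, design, adj)
        spec_p = bym.ModelSpec(spatial="bym", tau_fixed=(None, 1e8), sampler=settings)
        fit_p = bym.fit_model(spec_p, design, adj)
        np.testing.assert_allclose(fit_b.beta.mean(axis=0), fit_p.beta.mean(axis=0), atol=0.1)
        assert np.abs(fit_p.f_unstruc).max() < 0.01

    def test_posterior_concentrates_with_n(self):
        """Mean posterior SD of beta shrinks monotonically as the sample
        doubles (shared seed streams across sizes)."""
        import warnings

        sds = []
        for n_clusters in (25, 50, 100, 200):
            cfg = dp.ScenarioConfig(
                n_districts_rows=3, n_districts_cols=4, n_clusters=n_clusters,
                women_per_cluster_mean=20, displacement_on=False, seed=42,
            )
            dmap = dp.generate_district_lattice(3, 4, 30.0)
            adj = geo.build_adjacency(dmap)
            ds = dp.generate_survey(cfg, dmap, adj)
            spec = bym.ModelSpec(sampler=bym.SamplerSettings(n_iter=1500, n_burnin=500, n_thin=1, seed=7))
            design = bym.build_design(ds, spec, dict(ds.truth.cluster_district))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = bym.fit_model(spec, design, adj)
            sds.append(fit.beta.std(axis=0, ddof=1).mean())
        assert sds[0] > sds[1] > sds[2] > sds[3]

    def test_missing_seed_rejected(self, small_survey):
        _, _, adj, ds = small_survey
        spec = bym.ModelSpec(sampler=bym.SamplerSettings(n_iter=200, n_burnin=50, seed=None))
        design = bym.build_design(ds, spec, dict(ds.truth.cluster_district))
        with pytest.raises(ValueError, match="seed"):
            bym.fit_model(spec, design, adj)
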