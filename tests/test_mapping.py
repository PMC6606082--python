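"""District prediction (against a brute-force per-draw recomputation),
SD distribution summaries, choropleth export and the pipeline wiring."""

import json

import numpy as np
import pytest
from scipy.special import expit

import districtprev as dp
from districtprev import bym, geo, mapping


@pytest.fixture(scope="module")
def toy_fit():
    """Deterministic 3-district fit built from synthetic draws."""
    rng = np.random.default_rng(12)
    S = 400
    nodes = ["dA", "dB", "dC"]
    beta = np.column_stack([rng.normal(-0.3, 0.1, S), rng.normal(0.4, 0.1, S)])
    f_u = rng.normal(0, 0.2, (S, 3))
    f_v = rng.normal(0, 0.1, (S, 3))
    fit = bym.PosteriorFit(
        spec=bym.ModelSpec(sampler=bym.SamplerSettings(seed=1)),
        beta=beta, beta_names=["intercept", "urban"],
        f_struc=f_u, f_unstruc=f_v,
        tau_struc=np.ones(S), tau_unstruc=np.ones(S),
        district_order=nodes,
    )
    n = 40
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    dist = np.array([nodes[i % 3] for i in range(n)], dtype=object)
    y = rng.integers(0, 2, n).astype(float)
    design = bym.DesignMatrix(y=y, X=X, columns=["intercept", "urban"], district_ids=dist)
    return fit, design


class TestPredictDistrictPrevalence:
    def test_matches_bruteforce_recomputation(self, toy_fit):
        fit, design = toy_fit
        ests = dp.predict_district_prevalence(fit, design)
        f = fit.f_spat()
        for j, d in enumerate(fit.district_order):
            rows = design.district_ids == d
            per_draw = np.array([
                expit(design.X[rows] @ fit.beta[s] + f[s, j]).mean()
                for s in range(fit.n_draws)
            ])
            assert ests[j].mean == pytest.approx(per_draw.mean(), abs=1e-12)
            assert ests[j].sd == pytest.approx(per_draw.std(ddof=1), abs=1e-12)
            lo, hi = np.quantile(per_draw, [0.025, 0.975])
            assert ests[j].ci_width == pytest.approx(hi - lo, abs=1e-12)

    def test_bounds_always_in_unit_interval(self, toy_fit):
        fit, design = toy_fit
        for e in dp.predict_district_prevalence(fit, design):
            assert 0.0 <= e.q025 <= e.mean <= e.q975 <= 1.0
            assert e.ci_width <= 1.0

    def test_intercept_only_single_district_collapses(self):
        rng = np.random.default_rng(5)
        S = 300
        fit = bym.PosteriorFit(
            spec=bym.ModelSpec(sampler=bym.SamplerSettings(seed=1)),
            beta=rng.normal(0.2, 0.3, (S, 1)), beta_names=["intercept"],
            f_struc=rng.normal(0, 0.2, (S, 1)), f_unstruc=np.zeros((S, 1)),
            tau_struc=np.ones(S), tau_unstruc=np.ones(S), district_order=["d1"],
        )
        design = bym.DesignMatrix(y=np.ones(6), X=np.ones((6, 1)), columns=["intercept"],
                                  district_ids=np.array(["d1"] * 6, dtype=object))
        est = dp.predict_district_prevalence(fit, design, "d1")
        draws = expit(fit.beta[:, 0] + fit.f_struc[:, 0])
        s = dp.posterior_summary(draws)
        assert est.mean == pytest.approx(s.mean, abs=1e-12)
        assert est.ci_width == pytest.approx(s.ci_width, abs=1e-12)

    def test_empty_district_flagged_and_uses_national_composition(self, toy_fit):
        fit, design = toy_fit
        # remove district dC's women
        keep = design.district_ids != "dC"
        d2 = bym.DesignMatrix(y=design.y[keep], X=design.X[keep], columns=design.columns,
                              district_ids=design.district_ids[keep])
        ests = {e.district_id: e for e in dp.predict_district_prevalence(fit, d2)}
        assert ests["dC"].extrapolated and ests["dC"].n_women == 0
        assert not ests["dA"].extrapolated
        assert 0.0 <= ests["dC"].mean <= 1.0


class TestSDDistribution:
    @staticmethod
    def est(did, sd):
        return dp.DistrictEstimate(did, 0.4, sd, 0.3, 0.5, 0.2, 10)

    def test_identical_sds(self):
        s = dp.summarize_sd_distribution([self.est(f"d{i}", 0.04) for i in range(8)])
        assert all(v == pytest.approx(0.04) for v in s.values())

    def test_hand_values(self):
        s = dp.summarize_sd_distribution([self.est(f"d{i}", v) for i, v in enumerate([1, 2, 3, 4, 5])])
        assert s["min"] == 1 and s["median"] == 3 and s["mean"] == 3 and s["max"] == 5

    def test_quartiles_match_interpolation_oracle(self, rng):
        sds = rng.uniform(0.01, 0.08, 23)
        s = dp.summarize_sd_distribution([self.est(f"d{i}", v) for i, v in enumerate(sds)])
        srt = np.sort(sds)
        # linear interpolation convention
        def q(p):
            h = p * (len(srt) - 1)
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])
        assert s["q1"] == pytest.approx(q(0.25))
        assert s["q3"] == pytest.approx(q(0.75))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dp.summarize_sd_distribution([])


class TestChoropleth:
    def test_round_trip_properties(self, tmp_path):
        dmap = dp.generate_district_lattice(2, 3, 10.0)
        ests = [dp.DistrictEstimate(d, 0.1 * (i + 1), 0.01 * (i + 1), 0.05, 0.9, 0.85, 5)
                for i, d in enumerate(dmap.ids)]
        out = tmp_path / "map.geojson"
        dp.export_choropleth(dmap, ests, out)
        payload = json.loads(out.read_text())
        by_id = {f["properties"]["district_id"]: f["properties"] for f in payload["features"]}
        for e in ests:
            assert by_id[e.district_id]["mean"] == pytest.approx(e.mean)
            assert by_id[e.district_id]["ci_width"] == pytest.approx(e.ci_width)
        assert (tmp_path / "map_uncertainty.geojson").exists()

    def test_quantile_binning_balances_counts(self, tmp_path):
        dmap = dp.generate_district_lattice(5, 15, 10.0)  # 75 districts
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.2, 0.7, 75)
        ests = [dp.DistrictEstimate(d, vals[i], 0.02, 0.1, 0.9, 0.8, 5)
                for i, d in enumerate(dmap.ids)]
        out = tmp_path / "m.geojson"
        dp.export_choropleth(dmap, ests, out, bins="quantile", n_bins=5)
        payload = json.loads(out.read_text())
        from collections import Counter

        counts = Counter(f["properties"]["bin"] for f in payload["features"])
        assert sorted(counts.values()) == [15, 15, 15, 15, 15]

    def test_fixed_bins_overflow_explicit(self, tmp_path):
        dmap = dp.generate_district_lattice(1, 3, 10.0)
        ests = [dp.DistrictEstimate("d001", 0.2, 0.01, 0.1, 0.3, 0.2, 5),
                dp.DistrictEstimate("d002", 0.5, 0.01, 0.4, 0.6, 0.2, 5),
                dp.DistrictEstimate("d003", 0.95, 0.01, 0.9, 1.0, 0.1, 5)]
        out = tmp_path / "m.geojson"
        dp.export_choropleth(dmap, ests, out, bins="fixed", fixed_edges=[0.0, 0.3, 0.6])
        payload = json.loads(out.read_text())
        bins = [f["properties"]["bin"] for f in payload["features"]]
        assert bins[2] == "overflow"  # 0.95 beyond the last edge, not clamped

    def test_missing_estimate_rejected(self, tmp_path):
        dmap = dp.generate_district_lattice(1, 2, 10.0)
        ests = [dp.DistrictEstimate("d001", 0.2, 0.01, 0.1, 0.3, 0.2, 5)]
        with pytest.raises(ValueError, match="d002"):
            dp.export_choropleth(dmap, ests, tmp_path / "m.geojson")


class TestPipeline:
    CONFIG = """
simulate:
  n_districts_rows: 3
  n_districts_cols: 4
  cell_size_km: 30.0
  n_clusters: 40
  women_per_cluster_mean: 12
  seed: 5
sampler:
  n_iter: 600
  n_burnin: 200
  n_thin: 2
brackets: [lt20]
structures: [besag, bym]
"""

    def test_end_to_end_and_determinism(self, tmp_path):
        cfg = tmp_path / "pipe.yaml"
        cfg.write_text(self.CONFIG)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out1 = dp.run_pipeline(cfg, tmp_path / "run1")
            out2 = dp.run_pipeline(cfg, tmp_path / "run2")
        for name in ("model_comparison.csv", "district_estimates_lt20.csv",
                     "map_lt20.geojson", "sd_distribution.csv", "prevalence_total.csv"):
            assert (out1 / name).exists()
        m1 = json.loads((out1 / "manifest.json").read_text())
        m2 = json.loads((out2 / "manifest.json").read_text())
        assert m1["hashes"] == m2["hashes"]

    def test_invalid_config_fails_before_compute(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("sampler: {n_iter: 10}\n")
        with pytest.raises(ValueError, match="simulate|inputs"):
            dp.run_pipeline(cfg, tmp_path / "out")
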