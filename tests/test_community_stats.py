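import numpy as np
import pandas as pd
import pytest

import mycoweb.community_stats as cs
import mycoweb as mw


def make_profiles(rng, n=60):
    idx = [f"s{i}" for i in range(n)]
    x = rng.normal(size=n)
    return pd.DataFrame(
        {
            "sample_id": idx,
            "modularity_pos": np.abs(x) + 0.1,
            "clustering_pos": rng.uniform(0.2, 0.9, n),
            "avg_path_length_pos": rng.uniform(1, 3, n),
            "coexclusion_proportion": rng.uniform(0.001, 0.05, n),
        },
        index=idx,
    )


class TestPropertyCorrelations:
    def test_identity_and_monotone_transform(self):
        idx = [f"s{i}" for i in range(20)]
        x = np.linspace(0.1, 1, 20)
        prof = pd.DataFrame(
            {"modularity_pos": x, "clustering_pos": x**3, "coexclusion_proportion": -x},
            index=idx,
        )
        out = cs.property_correlations(prof, properties=list(prof.columns))
        lookup = out.set_index(["prop_x", "prop_y"])["r"]
        assert lookup[("modularity_pos", "clustering_pos")] == pytest.approx(1.0)
        assert lookup[("modularity_pos", "coexclusion_proportion")] == pytest.approx(-1.0)

    def test_relationship_rule_requires_strength_and_significance(self):
        rng = np.random.default_rng(0)
        prof = make_profiles(rng)
        strata = pd.Series(["ES"] * 30 + ["US"] * 30, index=prof.index)
        out = cs.property_correlations(prof, strata)
        weak = out[(out["r"].abs() < 0.3) & (out["stratum"] != "pooled")]
        grouped = weak.groupby(["prop_x", "prop_y"])["relationship"]
        # pairs weak in every stratum cannot be flagged
        for (a, b), grp in grouped:
            per_pair = out[(out.prop_x == a) & (out.prop_y == b) & (out.stratum != "pooled")]
            if (per_pair["r"].abs() <= 0.5).all():
                assert not per_pair["relationship"].any()

    def test_constant_property_skipped(self):
        prof = pd.DataFrame(
            {"modularity_pos": np.ones(12), "clustering_pos": np.arange(12.0)},
            index=[f"s{i}" for i in range(12)],
        )
        out = cs.property_correlations(prof, properties=list(prof.columns))
        assert out.empty


class TestEnvfit:
    def test_axis_aligned_variable(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(
            rng.normal(size=(30, 2)), columns=["NMDS1", "NMDS2"],
            index=[f"s{i}" for i in range(30)],
        )
        out = cs.envfit_vectors(scores, scores[["NMDS1"]].rename(columns={"NMDS1": "v"}),
                                n_perm=99, seed=0)
        row = out.iloc[0]
        assert row["r2"] == pytest.approx(1.0, abs=1e-9)
        assert abs(row["axis1"]) == pytest.approx(1.0, abs=1e-6)

    def test_four_point_toy_matches_regression_oracle(self):
        scores = pd.DataFrame(
            [[0, 0], [1, 0], [0, 1], [1, 1]], columns=["a1", "a2"],
            index=list("wxyz"), dtype=float,
        )
        v = pd.DataFrame({"v": [0.0, 2.0, 1.0, 4.0]}, index=list("wxyz"))
        out = cs.envfit_vectors(scores, v, n_perm=49, seed=0)
        x = scores.to_numpy() - scores.to_numpy().mean(axis=0)
        y = v["v"].to_numpy() - v["v"].mean()
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        oracle = ((x @ beta) ** 2).sum() / (y**2).sum()
        assert out.iloc[0]["r2"] == pytest.approx(oracle, abs=1e-12)

    def test_noise_variable_rarely_significant(self):
        rng = np.random.default_rng(2)
        calm = 0
        for i in range(20):
            scores = pd.DataFrame(rng.normal(size=(20, 2)), index=range(20))
            noise = pd.DataFrame({"v": rng.normal(size=20)}, index=range(20))
            p = cs.envfit_vectors(scores, noise, n_perm=199, seed=i).iloc[0]["p"]
            calm += p > 0.01
        assert calm >= 18


class TestVariationPartitioning:
    def _blocks(self, rng, n=80):
        return {
            "geo": pd.DataFrame(rng.normal(size=(n, 2)), columns=["lat", "lon"]),
            "weather": pd.DataFrame(rng.normal(size=(n, 2)), columns=["t", "h"]),
            "network": pd.DataFrame(rng.normal(size=(n, 2)), columns=["q", "c"]),
        }

    def test_single_block_response(self):
        rng = np.random.default_rng(3)
        blocks = self._blocks(rng, n=400)
        y = pd.DataFrame(
            blocks["geo"].to_numpy() @ np.array([[1.0, 0.2], [0.5, -1.0]])
            + 0.05 * rng.normal(size=(400, 2))
        )
        for b in blocks.values():
            b.index = y.index
        part = cs.variation_partitioning(y, blocks)
        total = part.total_explained()
        assert part.fractions["geo"] == pytest.approx(total, abs=0.02)
        assert abs(part.fractions["weather"]) < 0.02
        assert abs(part.fractions["network"]) < 0.02

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        blocks = self._blocks(rng)
        y = pd.DataFrame(rng.normal(size=(80, 2)))
        for b in blocks.values():
            b.index = y.index
        part = cs.variation_partitioning(y, blocks)
        assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_blocks_share_nothing(self):
        rng = np.random.default_rng(5)
        blocks = self._blocks(rng, n=400)
        y = pd.DataFrame(
            blocks["geo"].to_numpy()[:, :1] + blocks["weather"].to_numpy()[:, :1]
            + 0.1 * rng.normal(size=(400, 1))
        )
        for b in blocks.values():
            b.index = y.index
        part = cs.variation_partitioning(y, blocks)
        assert abs(part.fractions["geo&weather"]) < 0.05
        assert abs(part.fractions["geo&network&weather"]) < 0.02

    def test_block_order_invariant(self):
        rng = np.random.default_rng(6)
        blocks = self._blocks(rng)
        y = pd.DataFrame(rng.normal(size=(80, 2)))
        for b in blocks.values():
            b.index = y.index
        p1 = cs.variation_partitioning(y, blocks)
        p2 = cs.variation_partitioning(y, dict(reversed(list(blocks.items()))))
        for key, val in p1.fractions.items():
            assert p2.fractions[key] == pytest.approx(val, abs=1e-12)


class TestForwardSelect:
    def test_true_signal_selected_among_noise(self):
        rng = np.random.default_rng(7)
        hits = 0
        for i in range(20):
            n = 60
            cands = pd.DataFrame(
                rng.normal(size=(n, 5)), columns=[f"v{j}" for j in range(5)]
            )
            y = pd.DataFrame(
                np.column_stack([cands["v0"] * 2, -cands["v0"]]) + 0.3 * rng.normal(size=(n, 2)),
                index=cands.index,
            )
            sel = cs.forward_select(y, cands, alpha=0.05, n_perm=99, seed=i)
            hits += "v0" in sel
        assert hits >= 18

    def test_pure_noise_mostly_empty(self):
        rng = np.random.default_rng(8)
        empty = 0
        for i in range(20):
            cands = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
            y = pd.DataFrame(rng.normal(size=(50, 2)), index=cands.index)
            sel = cs.forward_select(y, cands, alpha=0.05, n_perm=99, seed=i)
            empty += len(sel) == 0
        assert empty >= 14

    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(9)
        cands = pd.DataFrame({"a": rng.normal(size=40)})
        cands["b"] = cands["a"]
        y = pd.DataFrame(cands["a"].to_numpy()[:, None] + 0.1 * rng.normal(size=(40, 1)),
                         index=cands.index)
        sel = cs.forward_select(y, cands, alpha=0.05, n_perm=99, seed=0)
        assert sel == ["a"]


class TestMixedModel:
    def _data(self, rng, n=180, sd=0.2, re_sd=0.3):
        regions = np.repeat([f"r{i}" for i in range(6)], n // 6)
        mgmt = rng.choice(["conventional", "organic", "biodynamic"], size=n)
        hum = rng.uniform(0.3, 0.9, n)
        means = {"conventional": 1.0, "organic": 0.6, "biodynamic": 0.2}
        re = dict(zip([f"r{i}" for i in range(6)], rng.normal(0, re_sd, 6)))
        logy = (
            np.array([means[m] for m in mgmt])
            + 0.5 * (hum - hum.mean()) / hum.std()
            + np.array([re[r] for r in regions])
            + rng.normal(0, sd, n)
        )
        idx = [f"s{i}" for i in range(n)]
        prof = pd.DataFrame({"resp": np.exp(logy)}, index=idx)
        meta = pd.DataFrame(
            {
                "management": mgmt,
                "region": regions,
                "country": "ES",
                "humidity": hum,
                "max_temperature": rng.uniform(10, 30, n),
                "wind_speed": rng.uniform(0, 5, n),
            },
            index=idx,
        )
        return prof, meta

    def test_recovers_management_cell_means(self):
        rng = np.random.default_rng(10)
        prof, meta = self._data(rng, n=300, sd=0.1, re_sd=0.05)
        fit = cs.fit_property_lmm(prof, meta, "resp", fixed=("humidity",))
        est = fit.fixed_effects["estimate"]
        conv = est[[i for i in est.index if "conventional" in i][0]]
        biod = est[[i for i in est.index if "biodynamic" in i][0]]
        assert conv - biod == pytest.approx(0.8, abs=0.15)

    def test_noise_free_linear_response_r2_one(self):
        rng = np.random.default_rng(11)
        prof, meta = self._data(rng, n=120, sd=1e-9, re_sd=0.0)
        fit = cs.fit_property_lmm(prof, meta, "resp", fixed=("humidity",))
        assert fit.marginal_r2 == pytest.approx(1.0, abs=0.01)

    def test_zero_random_effect_marginal_near_total(self):
        rng = np.random.default_rng(12)
        prof, meta = self._data(rng, n=240, sd=0.3, re_sd=0.0)
        fit = cs.fit_property_lmm(prof, meta, "resp", fixed=("humidity",))
        # with no region variance the marginal R2 equals the conditional one
        cond = (fit.marginal_r2 * (1) + fit.random_effect_var
                / (np.var(np.log(prof["resp"])) + 1e-12))
        assert fit.random_effect_var < 0.05
        assert 0 < fit.marginal_r2 <= 1


class TestTwoWayAnova:
    def test_balanced_toy_matches_hand_sums_of_squares(self):
        # 2x2 balanced design, 3 replicates per cell: Type II == classic SS
        rng = np.random.default_rng(13)
        rows = []
        cell_means = {("a", "x"): 1.0, ("a", "y"): 2.0, ("b", "x"): 3.0, ("b", "y"): 2.5}
        for (f1, f2), mu in cell_means.items():
            for r in range(3):
                rows.append({"management": f1, "country": f2, "resp": mu + 0.1 * rng.normal()})
        df = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
        prof = df[["resp"]]
        meta = df[["management", "country"]]
        table = cs.two_way_anova(prof, meta, "resp")
        y = df["resp"].to_numpy()
        grand = y.mean()
        a_means = df.groupby("management")["resp"].mean()
        b_means = df.groupby("country")["resp"].mean()
        ss_a = sum(6 * (a_means[l] - grand) ** 2 for l in a_means.index)
        ss_b = sum(6 * (b_means[l] - grand) ** 2 for l in b_means.index)
        assert table.loc["C(management)", "sum_sq"] == pytest.approx(ss_a, abs=1e-9)
        assert table.loc["C(country)", "sum_sq"] == pytest.approx(ss_b, abs=1e-9)

    def test_null_response_rarely_significant(self):
        rng = np.random.default_rng(14)
        calm = 0
        for i in range(40):
            n = 60
            df = pd.DataFrame(
                {
                    "management": rng.choice(["c", "o", "b"], n),
                    "country": rng.choice(["ES", "US"], n),
                    "resp": rng.normal(size=n),
                },
                index=[f"s{i}" for i in range(n)],
            )
            table = cs.two_way_anova(df[["resp"]], df[["management", "country"]], "resp")
            calm += table.loc["C(management)", "PR(>F)"] > 0.01
        assert calm >= 36

    def test_planted_effect_detected_without_interaction(self):
        rng = np.random.default_rng(15)
        n = 120
        mgmt = rng.choice(["c", "o", "b"], n)
        df = pd.DataFrame(
            {
                "management": mgmt,
                "country": rng.choice(["ES", "US"], n),
                "resp": np.where(mgmt == "c", 2.0, 0.0) + rng.normal(size=n) * 0.5,
            },
            index=[f"s{i}" for i in range(n)],
        )
        table = cs.two_way_anova(df[["resp"]], df[["management", "country"]], "resp")
        assert table.loc["C(management)", "PR(>F)"] < 0.01
        assert table.loc["C(management):C(country)", "PR(>F)"] > 0.01


class TestPathogenAnalysis:
    def test_absent_pathogens_refused(self, small_pipeline):
        presence = small_pipeline["presence"]
        profiles = mw.profile_all(small_pipeline["web"], presence)
        with pytest.raises(ValueError, match="no pathogen"):
            cs.pathogen_analysis(profiles, presence, ["not_a_real_otu"])

    def test_richness_matches_set_intersection(self, standard_pipeline):
        presence = standard_pipeline["presence"]
        truth = standard_pipeline["truth"]
        profiles = standard_pipeline["profiles"]
        pathogens = [o for o in truth.pathogen_flags[truth.pathogen_flags].index
                     if o in presence.otu_ids]
        result = cs.pathogen_analysis(profiles, presence, pathogens)
        for sid in presence.sample_ids[:10]:
            oracle = len(set(pathogens) & presence.species_of(sid))
            assert result.richness[sid] == oracle

    def test_probability_curve_monotone_in_planted_direction(self):
        rng = np.random.default_rng(16)
        n = 150
        prof = pd.DataFrame(
            {
                "clustering_pos": rng.uniform(0, 1, n),
                "modularity_pos": rng.uniform(0, 1, n),
                "avg_path_length_neg": rng.uniform(1, 3, n),
                "coexclusion_proportion": rng.uniform(0, 1, n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        eta = 2 - 4 * prof["coexclusion_proportion"]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        # fabricate a presence matrix with a single pathogen column matching y
        vals = np.column_stack([y.astype(np.uint8), np.ones(n, np.uint8)])
        presence = mw.PresenceMatrix(list(prof.index), ["path1", "other"], vals)
        res = cs.pathogen_analysis(prof, presence, ["path1"])
        assert res.coefficients.loc["coexclusion_proportion", "estimate"] < 0
        assert res.probability_curve["probability"].iloc[0] > res.probability_curve[
            "probability"
        ].iloc[-1]


class TestDiversityCorrelation:
    def test_perfect_antirank(self):
        prof = pd.DataFrame(
            {"modularity_pos": np.arange(10.0)}, index=[f"s{i}" for i in range(10)]
        )
        h = pd.Series(-np.arange(10.0), index=prof.index)
        out = cs.diversity_property_correlation(prof, h, properties=["modularity_pos"])
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(17)
        rs = []
        for _ in range(50):
            prof = pd.DataFrame(
                {"modularity_pos": rng.normal(size=30)}, index=range(30)
            )
            h = pd.Series(rng.normal(size=30), index=prof.index)
            rs.append(
                cs.diversity_property_correlation(prof, h, ["modularity_pos"]).iloc[0]["r"]
            )
        assert abs(np.mean(rs)) < 0.1


class TestEnvPca:
    def test_perfectly_correlated_pair_one_component(self):
        rng = np.random.default_rng(18)
        v = rng.uniform(1, 10, 40)
        meta = pd.DataFrame({"a": v, "b": v * 3}, index=range(40))
        _, _, explained = cs.env_pca(meta)
        assert explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(19)
        meta = pd.DataFrame(rng.uniform(1, 5, size=(60, 4)), columns=list("abcd"))
        _, loadings, _ = cs.env_pca(meta)
        gram = loadings.to_numpy().T @ loadings.to_numpy()
        assert np.allclose(gram, np.eye(4), atol=1e-9)

    def test_constant_variable_dropped(self):
        rng = np.random.default_rng(20)
        meta = pd.DataFrame({"a": rng.uniform(1, 5, 30), "b": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            scores, loadings, _ = cs.env_pca(meta)
        assert "b" not in loadings.index
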