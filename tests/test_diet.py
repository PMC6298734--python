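"""Diet grouping, Schoener's D, diversity indices and rarefaction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nichepart as nip
from nichepart import diet as dmod
from tests.conftest import random_composition


def _diet_rows(stomachs):
    """stomachs: list of (stomach_id, species, length, {taxon: weight})."""
    rows = []
    for sid, sp, length, prey in stomachs:
        if not prey:
            rows.append(dict(stomach_id=sid, haul_id="h1", species=sp,
                             fork_length_cm=length, fullness_code=1,
                             prey_taxon="", prey_weight_g=np.nan))
        for taxon, w in prey.items():
            rows.append(dict(stomach_id=sid, haul_id="h1", species=sp,
                             fork_length_cm=length, fullness_code=4,
                             prey_taxon=taxon, prey_weight_g=w))
    return pd.DataFrame(rows)


def _one_haul():
    return pd.DataFrame(
        dict(haul_id=["h1"], year=[2001], lon=[-150.0], lat=[55.0],
             depth_m=[100.0], temp_c=[5.0])
    )


class TestGroupStomachs:
    def _run(self, n_ph, n_atf, goa_grid, min_per_predator=3):
        stomachs = [
            (f"p{i}", "PH", 45, {"pollock": 10.0}) for i in range(n_ph)
        ] + [
            (f"a{i}", "ATF", 45, {"pollock": 5.0}) for i in range(n_atf)
        ]
        return dmod.group_stomachs(
            _diet_rows(stomachs), _one_haul(), goa_grid,
            min_per_predator=min_per_predator,
        )

    def test_threshold_edge_not_qualifying(self, goa_grid):
        _, qualifying = self._run(3, 2, goa_grid)
        assert qualifying == set()

    def test_threshold_met_qualifying(self, goa_grid):
        pooled, qualifying = self._run(3, 3, goa_grid)
        assert len(qualifying) == 1
        assert set(pooled["species"]) == {"PH", "ATF"}

    def test_empty_stomachs_do_not_count(self, goa_grid):
        stomachs = (
            [(f"p{i}", "PH", 45, {"pollock": 10.0}) for i in range(3)]
            + [("p_empty", "PH", 45, {})]
            + [(f"a{i}", "ATF", 45, {"pollock": 5.0}) for i in range(2)]
            + [("a_empty", "ATF", 45, {})]
        )
        _, qualifying = dmod.group_stomachs(
            _diet_rows(stomachs), _one_haul(), goa_grid
        )
        assert qualifying == set()

    def test_size_range_applied(self, goa_grid):
        stomachs = [(f"p{i}", "PH", 75, {"pollock": 10.0}) for i in range(5)]
        stomachs += [(f"a{i}", "ATF", 45, {"pollock": 5.0}) for i in range(5)]
        _, qualifying = dmod.group_stomachs(
            _diet_rows(stomachs), _one_haul(), goa_grid
        )
        assert qualifying == set()

    def test_matches_count_oracle(self, survey_tables, goa_grid):
        diet = survey_tables["stomachs"]
        hauls = survey_tables["hauls"]
        pooled, qualifying = dmod.group_stomachs(diet, hauls, goa_grid)
        # brute-force recount
        info = hauls.set_index("haul_id")[["year", "lon", "lat"]]
        dd = diet.merge(info, left_on="haul_id", right_index=True)
        dd = dd[~dmod.is_empty_stomach(dd)]
        dd = dd[(dd.fork_length_cm >= 30) & (dd.fork_length_cm <= 69)]
        dd["cell_id"] = goa_grid.locate(dd.lon.to_numpy(), dd.lat.to_numpy())
        expected = set()
        for (year, cell), grp in dd.groupby(["year", "cell_id"]):
            if cell == "unassigned":
                continue
            n_ph = grp.loc[grp.species == "PH", "stomach_id"].nunique()
            n_atf = grp.loc[grp.species == "ATF", "stomach_id"].nunique()
            if n_ph >= 3 and n_atf >= 3:
                expected.add((year, cell))
        assert qualifying == expected
        assert set(zip(pooled["year"], pooled["cell_id"])) <= expected


class TestPreyProportions:
    def test_forced_arithmetic(self):
        w = dmod.prey_proportions(pd.Series({"a": 10.0, "b": 30.0}))
        assert w["a"] == pytest.approx(0.25)
        assert w["b"] == pytest.approx(0.75)

    def test_single_taxon_identity(self):
        w = dmod.prey_proportions(pd.Series({"a": 4.2}))
        assert w["a"] == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            dmod.prey_proportions(pd.Series({"a": 0.0}))

    def test_matches_pooled_sum_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n_stomach = rng.integers(1, 8)
            taxa = [f"t{i}" for i in range(rng.integers(1, 6))]
            weights = {}
            for s in range(n_stomach):
                for t in taxa:
                    if rng.random() < 0.6:
                        weights[t] = weights.get(t, 0) + rng.exponential(5)
            if not weights:
                continue
            pooled = pd.Series(weights)
            w = dmod.prey_proportions(pooled)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            total = sum(weights.values())
            for t in weights:
                assert w[t] == pytest.approx(weights[t] / total)


class TestSchoener:
    def test_identical_compositions(self):
        w = pd.Series({"a": 0.4, "b": 0.6})
        assert dmod.schoener(w, w) == pytest.approx(1.0)

    def test_disjoint_compositions(self):
        assert dmod.schoener(
            pd.Series({"a": 1.0}), pd.Series({"b": 1.0})
        ) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        w_a = pd.Series({"x": 0.5, "y": 0.5, "z": 0.0})
        w_b = pd.Series({"x": 0.25, "y": 0.25, "z": 0.5})
        assert dmod.schoener(w_a, w_b) == pytest.approx(0.5)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            dmod.schoener(pd.Series({"a": 0.7}), pd.Series({"b": 1.0}))

    def test_symmetry_zero_padding_and_l1_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            wa = random_composition(rng, rng.integers(1, 8))
            wb = random_composition(rng, rng.integers(1, 8))
            d = dmod.schoener(wa, wb)
            assert 0.0 <= d <= 1.0 + 1e-12
            assert d == pytest.approx(dmod.schoener(wb, wa), abs=1e-12)
            # zero-padding with unobserved taxa changes nothing
            wa_pad = pd.concat([wa, pd.Series({"ghost": 0.0})])
            assert dmod.schoener(wa_pad, wb) == pytest.approx(d, abs=1e-12)
            # D + L1/2 == 1
            union = wa.index.union(wb.index)
            l1 = np.abs(
                wa.reindex(union, fill_value=0)
                - wb.reindex(union, fill_value=0)
            ).sum()
            assert d + 0.5 * l1 == pytest.approx(1.0, abs=1e-12)


class TestDiversity:
    def test_uniform_maximal_evenness(self):
        for q in (2, 5, 11):
            w = pd.Series(1.0 / q, index=[f"t{i}" for i in range(q)])
            assert dmod.shannon(w) == pytest.approx(math.log(q))
            assert dmod.pielou(w) == pytest.approx(1.0)

    def test_single_taxon(self):
        w = pd.Series({"a": 1.0})
        assert dmod.shannon(w) == 0.0
        assert math.isnan(dmod.pielou(w))

    def test_even_pair_is_ln2(self):
        w = pd.Series({"a": 0.5, "b": 0.5})
        assert dmod.shannon(w) == pytest.approx(math.log(2.0))


class TestRarefaction:
    def _table(self, stomach_taxa):
        rows = []
        for i, taxa in enumerate(stomach_taxa):
            for t in taxa:
                rows.append(dict(stomach_id=f"s{i}", haul_id="h1",
                                 species="PH", fork_length_cm=45,
                                 fullness_code=4, prey_taxon=t,
                                 prey_weight_g=1.0))
        return pd.DataFrame(rows)

    def test_endpoint_equals_observed_richness(self):
        diet = self._table([{"a"}, {"a", "b"}, {"c"}, {"b", "d"}])
        curve = dmod.rarefaction(diet, "PH", seed=0)
        assert curve["mean_taxa"].iloc[-1] == pytest.approx(4.0)
        assert curve["n_stomachs"].iloc[-1] == 4

    def test_flat_curve_single_shared_taxon(self):
        diet = self._table([{"a"}] * 6)
        curve = dmod.rarefaction(diet, "PH", seed=0)
        assert (curve["mean_taxa"] == 1.0).all()

    def test_nondecreasing_means(self):
        rng = np.random.default_rng(2)
        diet = self._table(
            [set(rng.choice(["a", "b", "c", "d", "e"],
                            rng.integers(1, 4), replace=False))
             for _ in range(15)]
        )
        curve = dmod.rarefaction(diet, "PH", n_resamples=400, seed=3)
        assert (np.diff(curve["mean_taxa"]) > -0.15).all()

    def test_matches_hypergeometric_expectation(self):
        # exact oracle: E[taxa at m] = sum_t 1 - C(n - n_t, m)/C(n, m)
        stomach_taxa = [{"a"}, {"a"}, {"b"}, {"b", "c"}, {"c"}, {"a", "c"}]
        diet = self._table(stomach_taxa)
        n = len(stomach_taxa)
        curve = dmod.rarefaction(diet, "PH", n_points=n, n_resamples=3000,
                                 seed=4)
        for _, row in curve.iterrows():
            m = int(row["n_stomachs"])
            expected = 0.0
            for taxon in {"a", "b", "c"}:
                n_t = sum(taxon in s for s in stomach_taxa)
                expected += 1.0 - (
                    math.comb(n - n_t, m) / math.comb(n, m)
                    if m <= n - n_t else 0.0
                )
            assert row["mean_taxa"] == pytest.approx(expected, abs=0.12)


class TestDisplayTables:
    def _compositions(self):
        return pd.DataFrame(
            dict(
                species=["PH"] * 3,
                area=["Kodiak"] * 3,
                size_class=["40-49"] * 3,
                prey_taxon=["pollock", "rare1", "rare2"],
                w=[0.985, 0.005, 0.010],
            )
        )

    def test_zero_threshold_is_identity(self):
        comps = self._compositions()
        out = dmod.aggregate_rare_taxa(comps, {"rare1": "fish"}, threshold=0.0)
        assert set(out["display_taxon"]) == set(comps["prey_taxon"])

    def test_rare_taxa_folded_and_mass_preserved(self):
        comps = self._compositions()
        with pytest.warns(UserWarning, match="rare2"):
            out = dmod.aggregate_rare_taxa(
                comps, {"rare1": "fish"}, threshold=0.011
            )
        assert set(out["display_taxon"]) == {"pollock", "fish", "other"}
        assert out["w"].sum() == pytest.approx(1.0)

    def test_all_rare_same_group_single_entry(self):
        comps = pd.DataFrame(
            dict(species=["PH"] * 2, area=["K"] * 2, size_class=["40-49"] * 2,
                 prey_taxon=["r1", "r2"], w=[0.6, 0.4])
        )
        out = dmod.aggregate_rare_taxa(
            comps, {"r1": "g", "r2": "g"}, threshold=1.1
        )
        assert len(out) == 1
        assert out["w"].iloc[0] == pytest.approx(1.0)

    def test_matches_fold_oracle(self):
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(10)]
        taxonomy = {t: ("fish" if i < 5 else "invert")
                    for i, t in enumerate(taxa)}
        w = rng.dirichlet(np.ones(10) * 0.5)
        comps = pd.DataFrame(
            dict(species="PH", area="K", size_class="40-49",
                 prey_taxon=taxa, w=w)
        )
        threshold = 0.05
        out = dmod.aggregate_rare_taxa(comps, taxonomy, threshold=threshold)
        expected = {}
        for t, wi in zip(taxa, w):
            key = taxonomy[t] if wi < threshold else t
            expected[key] = expected.get(key, 0.0) + wi
        got = dict(zip(out["display_taxon"], out["w"]))
        assert set(got) == set(expected)
        for k in expected:
            assert got[k] == pytest.approx(expected[k])

    def test_size_class_compositions_sum_to_one(self, survey_tables):
        out = dmod.size_class_compositions(
            survey_tables["stomachs"], survey_tables["hauls"]
        )
        sums = out.groupby(["species", "area", "size_class"])["w"].sum()
        assert np.allclose(sums, 1.0)
        labels = {f"{lo}-{hi}" for lo, hi in dmod.DISPLAY_SIZE_BINS}
        assert set(out["size_class"]) <= labels


class TestDietaryOverlapField:
    def test_end_to_end_d_approaches_one_with_matching_diets(self, goa_grid):
        # two predators generated from the same composition: D rises with n
        comp = {"any": [0.45, 0.35, 0.2]}
        results = {}
        for n in (3, 10, 100):
            stomachs = []
            rng = np.random.default_rng(n)
            for sp in ("PH", "ATF"):
                for i in range(n):
                    prey = {
                        f"t{j}": rng.gamma(2.0, comp["any"][j])
                        for j in range(3)
                    }
                    stomachs.append((f"{sp}{i}", sp, 45, prey))
            pooled, _ = dmod.group_stomachs(
                _diet_rows(stomachs), _one_haul(), goa_grid
            )
            d = dmod.dietary_overlap_field(pooled)
            results[n] = d["d"].iloc[0]
        assert results[3] <= results[10] + 0.1
        assert results[100] > 0.9
        assert all(0 <= v <= 1 for v in results.values())
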