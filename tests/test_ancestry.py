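import math

import numpy as np
import pandas as pd
import pytest

from skingwas.ancestry import (GeneSetEnrichment, RafFlag, collect_eqtl_targets,
                               aggregate_population_freqs, fit_raf_annotation_glm,
                               flag_raf_direction, geneset_enrichment,
                               locus_direction, raf_proportions)
from skingwas.errors import DegenerateInputError, DomainError
from skingwas.finemap import credible_set
from skingwas.gwas_io import EqtlRecord
from .test_finemap import make_locus, rec


def freq_table(rows):
    return pd.DataFrame(rows, columns=["variant_id", "raf_afr", "raf_eur",
                                       "n_pops_afr", "n_pops_eur"])


class TestFlags:
    # frequencies of known IL1-pathway credible variants: higher-AfrA,
    # exact-tie and higher-EurA cases
    @pytest.mark.parametrize("afr,eur,expected", [
        (0.63, 0.34, "afr_higher"),
        (0.29, 0.29, "tie"),
        (0.10, 0.22, "eur_higher"),
    ])
    def test_direction_is_strict_comparison(self, afr, eur, expected):
        table = freq_table([("v", afr, eur, 5, 5)])
        (flag,) = flag_raf_direction(table, ["v"])
        assert flag.direction == expected

    def test_missing_variants_listed(self):
        table = freq_table([("v", 0.5, 0.4, 5, 5)])
        with pytest.raises(DegenerateInputError, match="missing"):
            flag_raf_direction(table, ["v", "w"])

    def test_permutation_invariance(self, rng):
        rows = [(f"v{i}", float(rng.uniform()), float(rng.uniform()), 5, 5)
                for i in range(30)]
        table = freq_table(rows)
        ids = [r[0] for r in rows]
        flags = {f.variant_id: f.direction
                 for f in flag_raf_direction(table, ids)}
        shuffled = list(ids)
        rng.shuffle(shuffled)
        flags2 = {f.variant_id: f.direction
                  for f in flag_raf_direction(table, shuffled)}
        assert flags == flags2


class TestProportions:
    def test_variant_unit_arithmetic(self):
        flags = [RafFlag("a", "afr_higher"), RafFlag("b", "afr_higher"),
                 RafFlag("c", "eur_higher"), RafFlag("d", "tie")]
        props = raf_proportions(flags)
        assert props == {"afr_higher": 0.5, "eur_higher": 0.25, "tie": 0.25}

    def test_all_one_direction(self):
        props = raf_proportions([RafFlag("a", "afr_higher")] * 3)
        assert props == {"afr_higher": 1.0, "eur_higher": 0.0, "tie": 0.0}

    def test_locus_majority_rule(self):
        members = [rec(100), rec(200), rec(300)]
        cs = credible_set(make_locus(members))
        directions = {m.variant_id: d for m, d in
                      zip(members, ("afr_higher", "afr_higher", "eur_higher"))}
        assert locus_direction(cs, directions) == "afr_higher"

    def test_locus_tie_on_equal_counts(self):
        members = [rec(100), rec(200)]
        cs = credible_set(make_locus(members))
        directions = {members[0].variant_id: "afr_higher",
                      members[1].variant_id: "eur_higher"}
        assert locus_direction(cs, directions) == "tie"

    def test_proportions_sum_to_one(self, rng):
        dirs = rng.choice(["afr_higher", "eur_higher", "tie"], size=50)
        flags = [RafFlag(f"v{i}", d) for i, d in enumerate(dirs)]
        assert sum(raf_proportions(flags).values()) == pytest.approx(1.0)


class TestAggregation:
    def test_unweighted_mean_over_populations(self):
        pops = pd.DataFrame({
            "variant_id": ["v"] * 4,
            "population": ["YRI", "LWK", "CEU", "TSI"],
            "group": ["afr", "afr", "eur", "eur"],
            "raf": [0.6, 0.8, 0.2, 0.4],
        })
        out = aggregate_population_freqs(pops)
        assert out.loc[0, "raf_afr"] == pytest.approx(0.7)
        assert out.loc[0, "raf_eur"] == pytest.approx(0.3)
        assert out.loc[0, "n_pops_afr"] == 2

    def test_weighted_option(self):
        pops = pd.DataFrame({
            "variant_id": ["v"] * 2 + ["v"],
            "population": ["YRI", "LWK", "CEU"],
            "group": ["afr", "afr", "eur"],
            "raf": [0.6, 0.9, 0.2],
        })
        out = aggregate_population_freqs(pops, weights={"YRI": 2, "LWK": 1,
                                                        "CEU": 1})
        assert out.loc[0, "raf_afr"] == pytest.approx((2 * 0.6 + 0.9) / 3)


def _glm_data(rng, n=2000, log_or=0.0, base_rate=0.5):
    x = pd.DataFrame({
        "atac": rng.random(n) < 0.3,
        "eqtl": rng.random(n) < 0.3,
    }, index=[f"v{i}" for i in range(n)])
    logit = math.log(base_rate / (1 - base_rate)) + log_or * x["eqtl"].to_numpy()
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    flags = [RafFlag(f"v{i}", "afr_higher" if yi else "eur_higher")
             for i, yi in enumerate(y)]
    return flags, x


class TestGlm:
    def test_constant_predictor_is_typed_error(self, rng):
        flags, x = _glm_data(rng, n=200)
        x["const_mark"] = True
        with pytest.raises(DegenerateInputError, match="const_mark"):
            fit_raf_annotation_glm(flags, x)

    def test_complete_separation_is_typed_error(self):
        flags = [RafFlag(f"v{i}", "afr_higher" if i < 5 else "eur_higher")
                 for i in range(10)]
        x = pd.DataFrame({"mark": [True] * 5 + [False] * 5},
                         index=[f"v{i}" for i in range(10)])
        with pytest.raises(DegenerateInputError, match="separation"):
            fit_raf_annotation_glm(flags, x)

    def test_recovers_planted_effect(self, rng):
        flags, x = _glm_data(rng, n=20_000, log_or=0.34)
        (res,) = [r for r in fit_raf_annotation_glm(flags, x, mode="joint")
                  if r.term == "eqtl"]
        assert res.or_estimate == pytest.approx(math.exp(0.34), rel=0.15)
        assert res.p < 0.01

    def test_marginal_mode_fits_each_term(self, rng):
        flags, x = _glm_data(rng, n=2000)
        results = fit_raf_annotation_glm(flags, x, mode="marginal")
        assert sorted(r.term for r in results) == ["atac", "eqtl"]
        assert all(r.model == "marginal" for r in results)

    def test_ties_excluded_from_fit(self, rng):
        flags, x = _glm_data(rng, n=500)
        padded = flags + [RafFlag(f"t{i}", "tie") for i in range(100)]
        # tie variants are absent from x: would error if not excluded first
        assert fit_raf_annotation_glm(padded, x, mode="joint")

    def test_duplicate_consistent_flags_collapse(self, rng):
        flags, x = _glm_data(rng, n=500)
        doubled = flags + flags
        a = fit_raf_annotation_glm(flags, x)
        b = fit_raf_annotation_glm(doubled, x)
        assert [(r.term, r.or_estimate) for r in a] == \
            [(r.term, r.or_estimate) for r in b]

    def test_conflicting_duplicate_flags_rejected(self, rng):
        flags, x = _glm_data(rng, n=500)
        conflicted = flags + [RafFlag(flags[0].variant_id,
                                      "eur_higher" if flags[0].direction ==
                                      "afr_higher" else "afr_higher")]
        with pytest.raises(DegenerateInputError, match="conflicting"):
            fit_raf_annotation_glm(conflicted, x)


class TestGeneSetEnrichment:
    def test_worked_example_table_and_or(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        selected = {f"g{i}" for i in range(5)} | {"g90", "g91", "g92"}
        res = geneset_enrichment(selected, gene_set, universe)
        assert (res.hits, res.selected_size, res.set_size,
                res.universe_size) == (5, 8, 10, 100)
        assert res.or_estimate == pytest.approx(29.0)
        # oracle: brute-force hypergeometric tail summation
        tail = sum(math.comb(10, k) * math.comb(90, 8 - k)
                   for k in range(5, 9)) / math.comb(100, 8)
        assert res.p == pytest.approx(tail, rel=1e-12)
        assert res.p == pytest.approx(1.637e-4, rel=1e-3)

    def test_zero_hits(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(20)}
        selected = {f"g{i}" for i in range(40, 60)}
        res = geneset_enrichment(selected, gene_set, universe)
        assert res.hits == 0
        assert res.or_estimate < 1
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_term_size_filter_is_strict(self):
        universe = {f"g{i}" for i in range(1000)}
        big = {f"g{i}" for i in range(500)}
        with pytest.raises(DomainError, match="term-size"):
            geneset_enrichment({"g0"}, big, universe)
        ok = {f"g{i}" for i in range(499)}
        assert geneset_enrichment({"g0"}, ok, universe).set_size == 499

    def test_haldane_correction_only_on_zero_cells(self):
        universe = {f"g{i}" for i in range(20)}
        # all of the set selected: c = 0 -> correction kicks in, OR finite
        res = geneset_enrichment({"g0", "g1"}, {"g0", "g1"}, universe)
        assert math.isfinite(res.or_estimate) and res.or_estimate > 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            geneset_enrichment(set(), {"g1"}, {"g1", "g2"})
        with pytest.raises(DegenerateInputError):
            geneset_enrichment({"g1"}, {"g2"}, set())


class TestEqtlTargets:
    def _fixture(self):
        members = [rec(100), rec(200), rec(300)]
        cs = credible_set(make_locus(members))
        v1, v2, v3 = [m.variant_id for m in members]
        eqtl = [EqtlRecord(v1, "IL1A", 0.01), EqtlRecord(v1, "IL1B", 0.01),
                EqtlRecord(v2, "IL1A", 0.02), EqtlRecord(v2, "IL37", 0.02),
                EqtlRecord(v3, "KRT1", 0.01)]
        flags = [RafFlag(v1, "afr_higher"), RafFlag(v2, "afr_higher"),
                 RafFlag(v3, "eur_higher")]
        return [cs], eqtl, flags

    def test_union_of_matching_targets(self):
        sets, eqtl, flags = self._fixture()
        genes = collect_eqtl_targets(sets, eqtl, flags, "afr_higher")
        assert genes == {"IL1A", "IL1B", "IL37"}

    def test_opposite_direction_disjoint(self):
        sets, eqtl, flags = self._fixture()
        afr = collect_eqtl_targets(sets, eqtl, flags, "afr_higher")
        eur = collect_eqtl_targets(sets, eqtl, flags, "eur_higher")
        assert eur == {"KRT1"}
        assert afr.isdisjoint(eur)

    def test_no_match_warns_and_returns_empty(self):
        sets, eqtl, flags = self._fixture()
        with pytest.warns(UserWarning):
            assert collect_eqtl_targets(sets, eqtl, flags, "tie") == set()
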