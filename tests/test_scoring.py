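"""Enrichment indices, EI differences, trajectories, prevalence, correlation,
and candidate prioritization."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import twopan as tp
from twopan.genetics import AMINO_ACIDS
from twopan.scoring import ScoringParams, _trend
from conftest import make_cmap


def brute_force_ei(variant, cmap):
    """Independent position-by-position summation oracle."""
    total = 0
    for i, aa in enumerate(variant):
        total += int(cmap.matrix.loc[f"P{i + 1}", aa])
    return total


def rounds_from_proportions(arm, props, depth=100_000, variant="RQLARVYAHYL"):
    """RoundCounts series in which ``variant`` has the given percent
    proportions and a filler variant absorbs the rest."""
    rounds = []
    filler = "A" * len(variant)
    for rnd, pct in enumerate(props):
        n = round(depth * pct / 100.0)
        c = Counter({variant: n, filler: depth - n})
        if n == 0:
            del c[variant]
        rounds.append(
            tp.RoundCounts(arm, rnd, c, Counter({"designed": depth}), depth)
        )
    return rounds


class TestEnrichmentIndex:
    def test_paper_text_fixture_ptyr_value(self, text_fixture_maps):
        _, ptyr = text_fixture_maps
        assert tp.enrichment_index("RCSEGLYVHYL", ptyr) == 8

    def test_all_zero_map_gives_zero(self):
        cmap = make_cmap("sTyr", {})
        assert tp.enrichment_index("RCSEGLYVHYL", cmap) == 0

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        aas = list(AMINO_ACIDS)
        for _ in range(1000):
            variant = "".join(rng.choice(aas, size=11))
            entries = {
                f"{rng.choice(aas)}@P{p + 1}": int(rng.choice([-1, 1]))
                for p in rng.choice(11, size=rng.integers(0, 8), replace=False)
            }
            cmap = make_cmap("sTyr", entries)
            assert tp.enrichment_index(variant, cmap) == brute_force_ei(variant, cmap)

    def test_invalid_residue_names_position(self, text_fixture_maps):
        styr, _ = text_fixture_maps
        with pytest.raises(ValueError, match="P3"):
            tp.enrichment_index("RQ*ARVYAHYL", styr)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_bounds_and_additivity(self, data):
        rng_entries = data.draw(
            st.dictionaries(
                st.tuples(
                    st.sampled_from(list(AMINO_ACIDS)),
                    st.integers(min_value=1, max_value=11),
                ),
                st.sampled_from([-1, 1]),
                max_size=30,
            )
        )
        cmap = make_cmap(
            "sTyr", {f"{aa}@P{p}": v for (aa, p), v in rng_entries.items()}
        )
        variant = "".join(
            data.draw(
                st.lists(
                    st.sampled_from(list(AMINO_ACIDS)), min_size=11, max_size=11
                )
            )
        )
        ei = tp.enrichment_index(variant, cmap)
        assert -11 <= ei <= 11
        # point substitution changes EI by exactly the cell difference
        pos = data.draw(st.integers(min_value=0, max_value=10))
        new_aa = data.draw(st.sampled_from(list(AMINO_ACIDS)))
        mutated = variant[:pos] + new_aa + variant[pos + 1 :]
        expected_shift = int(cmap.matrix.iloc[pos][new_aa]) - int(
            cmap.matrix.iloc[pos][variant[pos]]
        )
        assert tp.enrichment_index(mutated, cmap) - ei == expected_shift


class TestEIDifference:
    @pytest.mark.parametrize("s,p,expected", [(9, 4, 5), (5, 5, 0), (10, 8, 2)])
    def test_table_arithmetic(self, s, p, expected):
        assert tp.ei_difference(s, p) == expected

    @pytest.mark.parametrize("x", range(-11, 12))
    def test_identity_pairs_are_zero(self, x):
        assert tp.ei_difference(x, x) == 0

    def test_antisymmetry(self):
        assert tp.ei_difference(9, 4) == -tp.ei_difference(4, 9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tp.ei_difference(12, 0)


class TestVariantTrajectory:
    @pytest.mark.parametrize(
        "props,expected",
        [
            ([0.01, 0.05, 0.2, 0.8, 2.0], "increasing"),
            ([1.0, 1.0, 1.0, 1.0, 1.0], "flat"),
            ([2.0, 1.0, 0.4, 0.1, 0.02], "decreasing"),
            ([0.0, 0.0, 0.0, 0.0, 0.0], "flat"),
        ],
    )
    def test_trend_rules(self, props, expected):
        rounds = rounds_from_proportions("sTyr", props)
        trj = tp.variant_trajectory("RQLARVYAHYL", rounds)
        assert trj.trend == expected
        assert trj.proportions == pytest.approx(props, abs=1e-3)

    def test_unobserved_variant_is_flat_zeros(self):
        rounds = rounds_from_proportions("sTyr", [1.0, 1.0, 1.0])
        trj = tp.variant_trajectory("W" * 11, rounds)
        assert trj.proportions == [0.0, 0.0, 0.0] and trj.trend == "flat"

    def test_saturation_dip_still_increasing(self):
        # winners competing at saturation may dip slightly in the last round
        assert _trend([0.1, 2.0, 14.2, 25.9, 24.0], ScoringParams()) == "increasing"

    def test_mixed_arms_rejected(self):
        rounds = rounds_from_proportions("sTyr", [1.0, 1.0])
        rounds += rounds_from_proportions("pTyr", [1.0])
        with pytest.raises(ValueError, match="single arm"):
            tp.variant_trajectory("RQLARVYAHYL", rounds)


class TestResiduePrevalence:
    def test_single_variant_always_100(self):
        rounds = rounds_from_proportions("sTyr", [100.0, 100.0], variant="RLLARVYAHCL")
        assert tp.residue_prevalence("C", 10, rounds) == [100.0, 100.0]

    def test_hand_arithmetic(self):
        c = Counter({"RLLARVYAHCL": 300, "RQLARVYAHYL": 700})
        rc = tp.RoundCounts("sTyr", 0, c, Counter({"designed": 1000}), 1000)
        assert tp.residue_prevalence("C", 10, [rc]) == [pytest.approx(30.0)]

    def test_null_simulation_prevalence_stable(self, design):
        # template residue prevalence stays within sampling noise of naive
        for seed in range(5):
            cfg = tp.ScenarioConfig(
                n_clones=4000, depth=20_000, seed=seed, plant=(), baseline_sigma=0.0
            )
            res = tp.run_scenario(cfg, emit_reads=False)
            rcs = [
                tp.sample_round_counts(pop, "sTyr", r, cfg.depth, 50 + r)
                for r, pop in enumerate(res.populations["sTyr"])
            ]
            prev = tp.residue_prevalence("Y", 7, rcs)
            assert abs(prev[-1] - prev[0]) < 5.0


class TestPearson:
    def test_perfect_linear(self):
        assert tp.pearson_correlation([1, 2, 3], [3, 5, 7]) == pytest.approx(1.0)
        assert tp.pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 5.5/n, sd product = sqrt(5 * 8.75)/n -> r = 0.8315
        r = tp.pearson_correlation([1, 2, 3, 4], [1, 3, 2, 5])
        assert r == pytest.approx(0.83, abs=0.005)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            tp.pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_short_input_errors(self):
        with pytest.raises(ValueError):
            tp.pearson_correlation([1, 2], [1, 2])


def two_arm_rounds(specs, depth=200_000, n_rounds=5):
    """Build both arms' RoundCounts from {variant: (styr_props, ptyr_props)}."""
    filler = "AAAAAAAAAAA"
    out = {}
    for arm_i, arm in enumerate(("sTyr", "pTyr")):
        rounds = []
        for rnd in range(n_rounds):
            c = Counter()
            for variant, props in specs.items():
                n = round(depth * props[arm_i][rnd] / 100.0)
                if n:
                    c[variant] = n
            c[filler] = depth - sum(c.values())
            rounds.append(
                tp.RoundCounts(arm, rnd, c, Counter({"designed": depth}), depth)
            )
        out[arm] = rounds
    return out


class TestPrioritize:
    def make_records(self, specs, cmap_s, cmap_p, params=ScoringParams()):
        rounds = two_arm_rounds(specs)
        return tp.score_variants(
            rounds["sTyr"], rounds["pTyr"], cmap_s, cmap_p, params,
            variants=sorted(specs),
        )

    def test_abundance_filter(self, text_fixture_maps):
        styr, ptyr = text_fixture_maps
        up = [0.01, 0.02, 0.05, 0.08, 0.09]  # increasing but under 0.1%
        down = [0.5, 0.2, 0.1, 0.05, 0.02]
        records = self.make_records(
            {"RCSEGLYVHYL": (up, down)}, styr, ptyr
        )
        rec = records[0]
        assert not rec.passes_abundance and rec.rank is None
        assert rec.passes_trend  # failed only the abundance filter

    def test_tie_break_by_final_proportion(self, text_fixture_maps):
        styr, ptyr = text_fixture_maps
        up_hi = [0.05, 0.1, 0.4, 0.8, 1.2]
        up_lo = [0.05, 0.1, 0.3, 0.5, 0.6]
        down = [0.5, 0.2, 0.1, 0.05, 0.02]
        # same variant composition twice -> identical EI keys, different final
        records = self.make_records(
            {"RCSEGLYVHYL": (up_lo, down), "RCSEGLYVHYW": (up_hi, down)},
            styr,
            ptyr,
        )
        # W@P11 vs L@P11: L enriched(+1) -> first variant has higher EI; to
        # test the proportion tie-break give both the same EI by masking P11
        by_rank = {r.rank: r for r in records if r.rank is not None}
        assert by_rank[1].variant == "RCSEGLYVHYL"  # higher EI wins first

    def test_equal_keys_resolved_by_abundance_then_name(self):
        cmap0 = make_cmap("sTyr", {})
        up_hi = [0.05, 0.1, 0.4, 0.8, 1.2]
        up_lo = [0.05, 0.1, 0.3, 0.5, 0.6]
        down = [0.5, 0.2, 0.1, 0.05, 0.02]
        recs = self.make_records(
            {"CCCCCCCCCCC": (up_lo, down), "DDDDDDDDDDD": (up_hi, down)},
            cmap0,
            make_cmap("pTyr", {}),
        )
        by_rank = {r.rank: r.variant for r in recs if r.rank is not None}
        assert by_rank[1] == "DDDDDDDDDDD"  # 1.2% final beats 0.6%
        # and with equal everything, lexicographic order decides
        recs2 = self.make_records(
            {"CCCCCCCCCCC": (up_hi, down), "DDDDDDDDDDD": (up_hi, down)},
            cmap0,
            make_cmap("pTyr", {}),
        )
        by_rank2 = {r.rank: r.variant for r in recs2 if r.rank is not None}
        assert by_rank2[1] == "CCCCCCCCCCC"

    def test_rising_counter_arm_excludes(self, text_fixture_maps):
        styr, ptyr = text_fixture_maps
        up = [0.05, 0.1, 0.4, 0.8, 1.2]
        records = self.make_records({"RCSEGLYVHYL": (up, up)}, styr, ptyr)
        rec = records[0]
        assert rec.passes_abundance and not rec.passes_trend and rec.rank is None

    def test_determinism(self, text_fixture_maps):
        styr, ptyr = text_fixture_maps
        up = [0.05, 0.1, 0.4, 0.8, 1.2]
        down = [0.5, 0.2, 0.1, 0.05, 0.02]
        specs = {"RCSEGLYVHYL": (up, down), "RCSEGVYVHYL": (up, down)}
        a = self.make_records(specs, styr, ptyr)
        b = self.make_records(specs, styr, ptyr)
        assert [(r.variant, r.rank, r.ei_difference) for r in a] == [
            (r.variant, r.rank, r.ei_difference) for r in b
        ]

    def test_missing_arm_data_flagged_and_excluded(self, text_fixture_maps):
        styr, ptyr = text_fixture_maps
        rec = tp.EIRecord("RCSEGLYVHYL", 10, 8, 2)
        out = tp.prioritize([rec], {}, {})
        assert out[0].rank is None and not out[0].passes_abundance

    def test_planted_specifics_recovered(self, small_scenario, small_analysis):
        ranked = [r.variant for r in small_analysis.ranked()]
        specifics = small_scenario.truth.planted_specific
        assert specifics.issubset(set(ranked[: len(specifics) + 1]))
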