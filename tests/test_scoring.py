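"""Scoring terms: fragmenter, substructure, references, suspects, RT."""

import math

import numpy as np
import pandas as pd
import pytest

from fragrank import (
    MatchSettings,
    Peak,
    RTModel,
    Spectrum,
    WeightConfig,
    combine_final,
    combined_reference_count,
    combined_reference_score,
    exclusion_score,
    fit_rt_model,
    fragmenter_score,
    get_precursor_type,
    inclusion_score,
    normalize_terms,
    rt_score,
    rt_score_from_logp,
    substructure_match_count,
    suspect_score,
)
from fragrank.scoring import attach_user_scores
from fragrank.spectra import MatchAssignment
from fragrank.fragments import FragmentRef


def _spec(peaks, neutral_mass, ptype="[M+H]+"):
    return Spectrum(
        peaks=peaks,
        neutral_precursor_mass=neutral_mass,
        precursor_type=get_precursor_type(ptype),
    )


def _assignment(peak, bde):
    frag = FragmentRef(0b1, 0b0, bde, 1)
    return MatchAssignment(peak, frag, 0, bde)


class TestFragmenterScore:
    def test_no_assignments_zero(self):
        spec = _spec([Peak(100.0, 1.0)], 200.0)
        assert fragmenter_score([], spec, WeightConfig()) == 0.0

    def test_unit_inputs_give_unit_score(self):
        ptype = get_precursor_type("[M+H]+")
        prec_mz = 200.0 + ptype.adduct_mass
        peak = Peak(prec_mz, 50.0)  # RelMass = 1, RelInt = 1
        spec = _spec([peak], 200.0)
        score = fragmenter_score([_assignment(peak, 1.0)], spec, WeightConfig())
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_single_assignment_formula_value(self):
        # 0.5^1.84 / 348^0.47, direct evaluation
        ptype = get_precursor_type("[M+H]+")
        prec_mz = 200.0 + ptype.adduct_mass
        peak = Peak(prec_mz / 2, 80.0)
        spec = _spec([peak], 200.0)
        score = fragmenter_score([_assignment(peak, 348.0)], spec, WeightConfig())
        assert score == pytest.approx(0.5**1.84 / 348**0.47, rel=1e-12)

    def test_equals_independent_oracle_on_random_sets(self):
        # independent re-evaluation of the sum, 100 random assignment sets
        rng = np.random.default_rng(17)
        w = WeightConfig()
        ptype = get_precursor_type("[M+H]+")
        for _ in range(100):
            neutral = float(rng.uniform(100, 500))
            prec_mz = neutral + ptype.adduct_mass
            n = int(rng.integers(1, 12))
            peaks = [
                Peak(float(rng.uniform(20, prec_mz)), float(rng.uniform(1, 1000)))
                for _ in range(n)
            ]
            spec = _spec(peaks, neutral)
            assigned = [
                _assignment(p, float(rng.uniform(100, 2000))) for p in peaks
            ]
            max_int = max(p.intensity for p in peaks)
            oracle = sum(
                (p.mz / prec_mz) ** w.alpha
                * (p.intensity / max_int) ** w.beta
                / a.matched_bde**w.gamma
                for p, a in zip(peaks, assigned)
            )
            got = fragmenter_score(assigned, spec, w)
            assert got == pytest.approx(oracle, rel=1e-12)


class TestNormalizeAndCombine:
    @pytest.mark.parametrize(
        "values, expected",
        [([2, 1, 0], [1.0, 0.5, 0.0]), ([0, 0], [0.0, 0.0]), ([7], [1.0])],
    )
    def test_normalize(self, values, expected):
        assert normalize_terms(values) == pytest.approx(expected)

    def test_normalized_in_unit_interval_with_max_attained(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = list(rng.uniform(0, 10, size=8))
            norm = normalize_terms(vals)
            assert all(0 <= v <= 1 for v in norm)
            assert max(norm) == pytest.approx(1.0)

    def test_combine_examples(self):
        w1 = WeightConfig({"a": 1.0})
        assert combine_final({"a": 0.7}, w1) == pytest.approx(0.7)
        w2 = WeightConfig({"a": 1.0, "b": 1.0})
        assert combine_final({"a": 1.0, "b": 0.5}, w2) == pytest.approx(1.5)
        w3 = WeightConfig({"a": 0.5, "b": 0.3, "c": 0.2})
        assert combine_final({"a": 0.3, "b": 0.4, "c": 0.2}, w3) == (
            pytest.approx(0.31)
        )

    def test_combine_order_invariant_and_linear(self):
        w = WeightConfig({"a": 0.4, "b": 0.6})
        assert combine_final({"a": 0.2, "b": 0.9}, w) == pytest.approx(
            combine_final({"b": 0.9, "a": 0.2}, w)
        )
        base = combine_final({"a": 0.2, "b": 0.9}, w)
        bumped = combine_final({"a": 0.2 + 0.1, "b": 0.9}, w)
        assert bumped - base == pytest.approx(0.4 * 0.1)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightConfig({"a": -0.5})

    def test_adding_candidate_never_raises_normalized_scores(self):
        vals = [3.0, 1.0, 2.0]
        before = normalize_terms(vals)
        after = normalize_terms(vals + [6.0])
        assert all(a <= b for a, b in zip(after[:3], before))


TABLE7_PATTERNS = ["N[CH2][CH3]", "NCCCC", "NC(C)CC", "NC(C)(C)C"]


class TestSubstructureScores:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("terbutylazine", 2),
            ("propazine", 0),
            ("secbutylazine", 2),
            ("triethazine", 1),
            ("nbutylazine", 2),
        ],
    )
    def test_isobar_hit_counts(self, triazines, name, expected):
        assert substructure_match_count(triazines[name], TABLE7_PATTERNS) == expected

    def test_binary_per_pattern(self, triazines):
        # triethazine carries two ethylamino groups but the ethylamino
        # pattern still counts once
        assert substructure_match_count(triazines["triethazine"], ["N[CH2][CH3]"]) == 1

    def test_empty_pattern_list(self, triazines):
        assert substructure_match_count(triazines["propazine"], []) == 0

    def test_invalid_smarts_named_in_error(self, triazines):
        with pytest.raises(ValueError, match="not-smarts"):
            substructure_match_count(triazines["propazine"], ["not-smarts("])

    def test_inclusion_score_normalized(self):
        assert inclusion_score([2, 1, 0]) == pytest.approx([1.0, 0.5, 0.0])
        assert inclusion_score([0, 0, 0]) == [0.0, 0.0, 0.0]

    def test_exclusion_score_with_zero_guard(self):
        assert exclusion_score([0, 2], 2) == pytest.approx([1.0, 0.0])
        assert exclusion_score([2, 2], 2) == [0.0, 0.0]


class TestReferenceScores:
    def test_worked_sum_from_four_sources(self):
        sources = ("CRC", "CERC", "CRSC", "CDC")
        counts = {"CRC": 94, "CERC": 15, "CRSC": 7, "CDC": 70}
        assert combined_reference_count(counts, sources) == 186

    def test_secondary_sums(self):
        sources = ("CRC", "CERC", "CRSC", "CDC")
        assert combined_reference_count(
            {"CRC": 179, "CERC": 1, "CRSC": 0, "CDC": 40}, sources
        ) == 220
        assert combined_reference_count(
            {"CRC": 32, "CERC": 0, "CRSC": 0, "CDC": 21}, sources
        ) == 53

    def test_single_source_selection(self):
        assert combined_reference_count(
            {"PubChemNumberPatents": 3, "PubChemPubMedCount": 9},
            ("PubChemNumberPatents",),
        ) == 3

    def test_missing_counts_default_to_zero(self):
        assert combined_reference_count({}, ("PubChemNumberPatents",)) == 0

    def test_normalization_over_candidates(self):
        raw, norm = combined_reference_score(
            [{"A": 186}, {"A": 220}, {"A": 53}], ("A",)
        )
        assert raw == [186, 220, 53]
        assert norm == pytest.approx([186 / 220, 1.0, 53 / 220])

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            combined_reference_count({"A": 1}, ())


class TestSuspectScore:
    def test_listed_and_unlisted(self):
        suspects = frozenset({"FZXISNSWEXTPMF"})
        assert suspect_score("FZXISNSWEXTPMF", suspects) == 1
        assert suspect_score("WJNRPILHGGKWCK", suspects) == 0

    def test_empty_set(self):
        assert suspect_score("FZXISNSWEXTPMF", frozenset()) == 0


class TestRTModel:
    def test_exact_line_recovered(self):
        with pytest.warns(UserWarning):
            m = fit_rt_model([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert m.slope == pytest.approx(1.0, abs=1e-12)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        rts = rng.uniform(1, 20, size=25)
        logps = 0.31 * rts - 0.8 + rng.normal(0, 0.4, size=25)
        m = fit_rt_model(list(zip(rts, logps)))
        x = np.column_stack([rts, np.ones_like(rts)])
        beta = np.linalg.solve(x.T @ x, x.T @ logps)
        assert m.slope == pytest.approx(beta[0], rel=1e-9)
        assert m.intercept == pytest.approx(beta[1], rel=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_rt_model([(1.0, 1.0)])

    def test_identical_rts_rejected(self):
        with pytest.raises(ValueError):
            fit_rt_model([(2.0, 1.0), (2.0, 3.0)])

    def test_few_points_warn(self):
        with pytest.warns(UserWarning, match="ten"):
            fit_rt_model([(1.0, 1.0), (2.0, 1.5), (3.0, 2.2)])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            RTModel(1.0, 0.0, sigma=0.0)


class TestRTScore:
    @pytest.mark.parametrize(
        "pred, cand, expected",
        [
            # worked isobar example, log P row (predicted 3.17)
            (3.17, 1.65, 0.159),
            (3.17, 2.75, 0.256),
            (3.17, 2.28, 0.223),
            # log D row (predicted 2.18)
            (2.18, 1.63, 0.249),
            (2.18, 0.97, 0.192),
            (2.18, 2.19, 0.266),
        ],
    )
    def test_printed_densities(self, pred, cand, expected):
        assert round(rt_score_from_logp(pred, cand, 1.5), 3) == expected

    def test_maximum_at_zero_deviation(self):
        peak = rt_score_from_logp(2.0, 2.0, 1.5)
        assert peak == pytest.approx(1 / (1.5 * math.sqrt(2 * math.pi)))

    def test_symmetric_and_strictly_decreasing(self):
        devs = [0.0, 0.3, 0.9, 1.7, 3.0]
        vals = [rt_score_from_logp(2.0, 2.0 + d, 1.5) for d in devs]
        assert vals == sorted(vals, reverse=True)
        for d in devs:
            assert rt_score_from_logp(2.0, 2.0 + d, 1.5) == pytest.approx(
                rt_score_from_logp(2.0, 2.0 - d, 1.5)
            )

    def test_model_prediction_feeds_density(self):
        m = RTModel(slope=0.5, intercept=0.0, sigma=1.5)
        assert rt_score(m, 6.34, 1.65) == pytest.approx(
            rt_score_from_logp(3.17, 1.65, 1.5)
        )


class TestUserScores:
    def test_columns_become_terms(self):
        df = pd.DataFrame({"Identifier": ["a", "b"], "UserLogP": [1.5, 2.0]})
        out = attach_user_scores(df, ["UserLogP"])
        assert out == {"UserLogP": [1.5, 2.0]}

    def test_missing_column_named(self):
        df = pd.DataFrame({"Identifier": ["a"]})
        with pytest.raises(ValueError, match="CFMID"):
            attach_user_scores(df, ["CFMID"])

    def test_non_numeric_cell_named(self):
        df = pd.DataFrame({"S": ["x"]})
        with pytest.raises(ValueError, match="'S'"):
            attach_user_scores(df, ["S"])

    def test_two_fragmenter_combination(self):
        # external fragmenter probabilities combined with the built-in
        # score at weights 0.67 / 0.33
        w = WeightConfig({"FragmenterScore": 0.67, "CFMID": 0.33})
        terms = {"FragmenterScore": 1.0, "CFMID": 0.5}
        assert combine_final(terms, w) == pytest.approx(0.67 + 0.33 * 0.5)
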