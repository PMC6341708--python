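"""Scoring engine: indicator fractions, QD/overall scores, rankings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from etiqh.scoring import (
    assessment_diagnostics,
    compare_rankings,
    fraction_met,
    qd_score,
    rank_facilities,
    score_all,
    score_facility,
)
from etiqh.types import IndicatorSpec, catalog_frame

from _oracle import oracle_fraction, oracle_scorecard
from conftest import make_responses


class TestFractionMet:
    @pytest.mark.parametrize(
        "answers,expected",
        [
            (["yes"], 1.0),
            (["yes", "no"], 0.5),
            (["na", "na"], None),
            (["yes", "yes", "no"], 2 / 3),
            (["yes", "na", "no"], 0.5),  # NA neutral among binary answers
            ([0.5, 1.0], 0.75),
            (["0.5", "na"], 0.5),
            ([0.0, 0.0], 0.0),
        ],
    )
    def test_examples(self, answers, expected):
        got = fraction_met(answers)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    @pytest.mark.parametrize(
        "bad", [[], ["yes", 0.5], ["maybe"], [1.5], [-0.1]]
    )
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            fraction_met(bad)

    def test_matches_oracle_on_random_lists(self):
        rng = np.random.default_rng(0)
        tokens = ["yes", "no", "na"]
        for _ in range(200):
            ans = list(rng.choice(tokens, size=rng.integers(1, 6)))
            got = fraction_met(ans)
            exp = oracle_fraction(ans)
            assert (got is None) == (exp is None)
            if exp is not None:
                assert got == pytest.approx(exp)


class TestFractionMetProperties:
    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["yes", "no", "na"]), min_size=1, max_size=10))
    def test_binary_lists_bounded_and_match_oracle(self, answers):
        got = fraction_met(answers)
        exp = oracle_fraction(answers)
        if exp is None:
            assert got is None
        else:
            assert 0.0 <= got <= 1.0
            assert got == pytest.approx(exp)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_graded_lists_average(self, values):
        assert fraction_met(values) == pytest.approx(float(np.mean(values)))

    @settings(deadline=None, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_order_invariance(self, perm):
        answers = ["yes", "yes", "no", "na", "yes", "no", "na", "no"]
        shuffled = [answers[i] for i in perm]
        assert fraction_met(shuffled) == pytest.approx(fraction_met(answers))


class TestRankingProperties:
    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            min_size=1,
            max_size=20,
        )
    )
    def test_ranks_are_a_permutation(self, scores):
        cards = pd.DataFrame(
            {
                "facility": [f"f{i:02d}" for i in range(len(scores))],
                "year": 2014,
                "overall": scores,
            }
        )
        ranking = rank_facilities(cards)
        df = ranking.as_frame()
        assert sorted(df["rank"]) == list(range(1, len(scores) + 1))
        # descending scores along the rank order
        assert (df.sort_values("rank")["score"].diff().dropna() <= 0).all()


class TestQdScore:
    @pytest.fixture()
    def two_indicator_catalog(self):
        return catalog_frame(
            [
                IndicatorSpec(id="a", section="QD1", weight=5),
                IndicatorSpec(id="b", section="QD1", weight=1),
            ]
        )

    def test_weighted_hand_example(self, two_indicator_catalog):
        # weights {5,1}, fractions {1,0}: 100 * 5/6
        resp = make_responses(
            [("f", 2014, "a", "yes"), ("f", 2014, "b", "no")]
        )
        got = qd_score(two_indicator_catalog, resp, "f", 2014, {"QD1"}, weighted=True)
        assert got == pytest.approx(100 * 5 / 6, abs=1e-9)

    def test_unweighted_hand_example(self, two_indicator_catalog):
        resp = make_responses(
            [("f", 2014, "a", "yes"), ("f", 2014, "b", "no")]
        )
        got = qd_score(two_indicator_catalog, resp, "f", 2014, {"QD1"}, weighted=False)
        assert got == pytest.approx(50.0)

    def test_all_met_is_100(self, two_indicator_catalog):
        resp = make_responses(
            [("f", 2014, "a", "yes"), ("f", 2014, "b", "yes")]
        )
        assert qd_score(
            two_indicator_catalog, resp, "f", 2014, {"QD1"}
        ) == pytest.approx(100.0)

    def test_nothing_assessed_signals(self, two_indicator_catalog):
        resp = make_responses([("f", 2014, "a", "na")])
        with pytest.raises(ValueError, match="no assessed indicator"):
            qd_score(two_indicator_catalog, resp, "f", 2014, {"QD1"})


class TestScoreFacility:
    def test_all_yes_scores_100(self, six_qd_catalog):
        resp = make_responses(
            [("f", 2014, f"{s}_001", "yes")
             for s in ("QD1", "QD2", "QD3A", "QD4", "QD5", "QD6")]
        )
        card = score_facility(six_qd_catalog, resp, "f", 2014)
        assert card.overall == pytest.approx(100.0)
        assert all(v == pytest.approx(100.0) for v in card.qd_scores.values())

    def test_overall_is_mean_of_six_qds(self, six_qd_catalog):
        # fractions 0.9,0.8,...,0.4 via repeated answers
        rows = []
        fracs = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        for s, f in zip(("QD1", "QD2", "QD3A", "QD4", "QD5", "QD6"), fracs):
            rows += [("f", 2014, f"{s}_001", "yes")] * int(f * 10)
            rows += [("f", 2014, f"{s}_001", "no")] * (10 - int(f * 10))
        card = score_facility(six_qd_catalog, resp := make_responses(rows), "f", 2014)
        assert card.overall == pytest.approx(65.0)

    def test_empty_assessment_signals(self, six_qd_catalog):
        with pytest.raises(ValueError, match="empty assessment"):
            score_facility(six_qd_catalog, make_responses([]), "f", 2014)

    def test_extra_failed_indicator_lowers_score(self):
        catalog = catalog_frame(
            [
                IndicatorSpec(id="a", section="QD1", weight=3),
                IndicatorSpec(id="b", section="QD1", weight=2),
            ]
        )
        base = [("f", 2014, "a", "yes")]
        extra = base + [("g", 2014, "a", "yes"), ("g", 2014, "b", "no")]
        rows = base + [(r[0].replace("f", "g"), *r[1:]) for r in extra[1:]]
        lean = score_facility(catalog, make_responses(base), "f", 2014)
        loaded = score_facility(
            catalog,
            make_responses(
                [("g", 2014, "a", "yes"), ("g", 2014, "b", "no")]
            ),
            "g",
            2014,
        )
        _, oracle_lean = oracle_scorecard(catalog, make_responses(base), "f", 2014)
        assert lean.overall == pytest.approx(oracle_lean)
        assert loaded.overall < lean.overall

    def test_undefined_qd_drops_from_overall(self, six_qd_catalog):
        # only 2 of 6 QDs assessed: overall averages the defined ones
        resp = make_responses(
            [("f", 2014, "QD1_001", "yes"), ("f", 2014, "QD2_001", "no")]
        )
        card = score_facility(six_qd_catalog, resp, "f", 2014)
        assert card.overall == pytest.approx(50.0)
        assert np.isnan(card.qd_scores["QD4"])

    def test_qd3_pooled_vs_submean(self):
        catalog = catalog_frame(
            [
                IndicatorSpec(id="a", section="QD3A", weight=1),
                IndicatorSpec(id="b1", section="QD3B", weight=1),
                IndicatorSpec(id="b2", section="QD3B", weight=1),
                IndicatorSpec(id="b3", section="QD3B", weight=1),
            ]
        )
        resp = make_responses(
            [
                ("f", 2014, "a", "no"),
                ("f", 2014, "b1", "yes"),
                ("f", 2014, "b2", "yes"),
                ("f", 2014, "b3", "yes"),
            ]
        )
        pooled = score_facility(catalog, resp, "f", 2014, qd3="pooled")
        submean = score_facility(catalog, resp, "f", 2014, qd3="submean")
        assert pooled.qd_scores["QD3"] == pytest.approx(75.0)  # 3 of 4 pooled
        assert submean.qd_scores["QD3"] == pytest.approx(50.0)  # mean(0, 100)


class TestRanking:
    def test_printed_dispensary_scores_reproduce_ranks(self):
        scores = {"A": 76, "B": 83, "C": 66, "D": 79, "E": 57, "F": 52}
        cards = pd.DataFrame(
            {"facility": list(scores), "year": 2014, "overall": list(scores.values())}
        )
        ranking = rank_facilities(cards)
        assert ranking.rank_of().to_dict() == {
            "B": 1, "D": 2, "A": 3, "C": 4, "E": 5, "F": 6
        }

    def test_single_facility(self):
        cards = pd.DataFrame({"facility": ["x"], "year": 2014, "overall": [50.0]})
        assert rank_facilities(cards).entries == (("x", 1, 50.0),)

    def test_tie_broken_by_facility_id(self):
        cards = pd.DataFrame(
            {"facility": ["b", "a"], "year": 2014, "overall": [60.0, 60.0]}
        )
        assert rank_facilities(cards).rank_of().to_dict() == {"a": 1, "b": 2}

    def test_mixed_years_signal(self):
        cards = pd.DataFrame(
            {"facility": ["a", "b"], "year": [2013, 2014], "overall": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="year"):
            rank_facilities(cards)


class TestCompareRankings:
    @staticmethod
    def _ranking(ranks):
        from etiqh.scoring import Ranking

        return Ranking(tuple((f, r, float(100 - r)) for f, r in ranks.items()))

    def test_worked_example_rho(self):
        # hand computation: rho = 1 - 6*sum(d^2)/(n^3 - n), d = (2,1,1,2,0,0)
        qual = self._ranking({c: i + 1 for i, c in enumerate("ABCDEF")})
        quant = self._ranking(dict(zip("ABCDEF", [3, 1, 4, 2, 5, 6])))
        d2 = sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4, 5, 6], [3, 1, 4, 2, 5, 6]))
        by_hand = 1 - 6 * d2 / (6 * (6**2 - 1))
        rep = compare_rankings(qual, quant)
        assert by_hand == pytest.approx(0.714285714, abs=1e-9)
        assert rep.spearman_rho == pytest.approx(by_hand, abs=1e-9)
        assert rep.max_displacement == 2

    def test_identical_rankings(self):
        r = self._ranking(dict(zip("ABC", [1, 2, 3])))
        rep = compare_rankings(r, r)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.kendall_tau == pytest.approx(1.0)
        assert rep.max_displacement == 0

    def test_exact_reversal(self):
        a = self._ranking(dict(zip("ABCDEF", [1, 2, 3, 4, 5, 6])))
        b = self._ranking(dict(zip("ABCDEF", [6, 5, 4, 3, 2, 1])))
        assert compare_rankings(a, b).spearman_rho == pytest.approx(-1.0)

    def test_facility_mismatch_signals(self):
        a = self._ranking({"A": 1, "B": 2})
        b = self._ranking({"A": 1, "C": 2})
        with pytest.raises(ValueError, match="facility"):
            compare_rankings(a, b)


class TestDiagnostics:
    def test_counts_and_average(self):
        resp = make_responses(
            [("f", 2014, "a", "yes"), ("f", 2014, "b", "yes")]
        )
        assert assessment_diagnostics(resp, "f", 2014) == (2, 1.0)

    def test_repeated_answers(self):
        resp = make_responses(
            [("f", 2014, "a", "yes")]
            + [("f", 2014, "b", "no")] * 3
        )
        assert assessment_diagnostics(resp, "f", 2014) == (2, 2.0)

    def test_recovers_generator_answer_distribution(self, default_dataset):
        # multi-answer sections draw 1..3 answers uniformly; singles elsewhere
        cfg, catalog, roster, responses, _ = default_dataset
        multi = catalog[catalog["section"].isin(["QD3A", "QD6"])]["id"]
        sub = responses[
            responses["indicator"].isin(set(multi)) & (responses["answer"] != "na")
        ]
        per = sub.groupby(["facility", "year", "indicator"]).size()
        assert per.mean() == pytest.approx(
            2.0, abs=max(0.02, 3 * per.std() / np.sqrt(len(per)))
        )


class TestScoringInvariants:
    """Structural invariants of the scoring engine on synthetic data."""

    def test_scores_in_range(self, small_dataset):
        _, catalog, _, responses, _ = small_dataset
        cards = score_all(catalog, responses)
        qd_cols = [f"QD{i}" for i in range(1, 7)]
        vals = cards[qd_cols + ["overall"]].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        assert (vals >= 0).all() and (vals <= 100).all()

    def test_all_yes_and_all_no_extremes(self, small_dataset):
        _, catalog, _, responses, _ = small_dataset
        for token, target in (("yes", 100.0), ("no", 0.0)):
            forced = responses.copy()
            mask = forced["answer"].isin(["yes", "no"]) | forced[
                "answer"
            ].str.fullmatch(r"[0-9.]+")
            forced.loc[mask, "answer"] = token
            cards = score_all(catalog, forced)
            assert cards["overall"].round(9).eq(target).all()

    def test_weight_neutrality(self, small_dataset):
        _, catalog, _, responses, _ = small_dataset
        flat = catalog.assign(weight=3)
        w = score_all(flat, responses, weighted=True)
        u = score_all(flat, responses, weighted=False)
        assert np.allclose(w["overall"], u["overall"], atol=1e-9)

    def test_permutation_invariance(self, small_dataset):
        _, catalog, _, responses, _ = small_dataset
        rng = np.random.default_rng(3)
        shuffled = responses.sample(frac=1, random_state=7).reset_index(drop=True)
        cat_shuffled = catalog.sample(frac=1, random_state=8).reset_index(drop=True)
        a = score_all(catalog, responses).set_index(["facility", "year"])
        b = score_all(cat_shuffled, shuffled).set_index(["facility", "year"])
        assert np.allclose(
            a["overall"], b["overall"].reindex(a.index), atol=1e-9
        )

    def test_na_neutrality(self, small_dataset):
        from etiqh.io import ensure_values

        _, catalog, _, responses, _ = small_dataset
        responses = ensure_values(responses)
        fractions = responses.groupby("indicator")["value"].count()
        all_na = fractions[fractions == 0].index
        pruned = responses[~responses["indicator"].isin(set(all_na))]
        a = score_all(catalog, responses).set_index(["facility", "year"])
        b = score_all(catalog, pruned).set_index(["facility", "year"])
        assert np.allclose(a["overall"], b.reindex(a.index)["overall"], atol=1e-9)

    def test_monotone_in_single_flip(self, small_dataset):
        _, catalog, _, responses, _ = small_dataset
        rng = np.random.default_rng(5)
        no_rows = responses.index[responses["answer"] == "no"]
        base = score_all(catalog, responses).set_index(["facility", "year"])
        for row in rng.choice(no_rows, size=5, replace=False):
            flipped = responses.copy()
            flipped.loc[row, "answer"] = "yes"
            cards = score_all(catalog, flipped).set_index(["facility", "year"])
            diff = cards["overall"] - base["overall"]
            assert (diff > -1e-12).all() and diff.sum() > 0

    def test_oracle_equivalence(self, small_dataset):
        _, catalog, _, responses, _ = small_dataset
        cards = score_all(catalog, responses).set_index(["facility", "year"])
        rng = np.random.default_rng(9)
        keys = rng.choice(len(cards), size=min(30, len(cards)), replace=False)
        for i in keys:
            fac, year = cards.index[i]
            qd_scores, overall = oracle_scorecard(catalog, responses, fac, year)
            assert cards.loc[(fac, year), "overall"] == pytest.approx(
                overall, abs=1e-9
            )
            for qd, val in qd_scores.items():
                assert cards.loc[(fac, year), qd] == pytest.approx(val, abs=1e-9)
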