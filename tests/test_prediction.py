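import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ifnscore import (
    CohortTable,
    IfnResponseModel,
    PredictionError,
    apply_cutoff,
    as_percent,
    roc_curve,
    select_cutoff,
    stratified_predict,
)
from ifnscore.examples import published_confusion_cohort

from conftest import auc_by_pair_counting, brute_force_cutoff


def labelled(pos, neg):
    """Scores + responder labels; pos = non-responders, neg = responders."""
    s = {f"n{i}": v for i, v in enumerate(pos)} | {f"r{i}": v for i, v in enumerate(neg)}
    resp = {k: k.startswith("r") for k in s}
    return pd.Series(s, dtype=float), pd.Series(resp)


class TestRocCurve:
    @pytest.mark.parametrize(
        "pos, neg, auc",
        [
            ([2, 3], [0, 1], 1.0),  # perfect separation
            ([1, 3], [2], 0.5),  # one concordant of two pairs
            ([1, 1], [1, 1], 0.5),  # all tied: each pair contributes 1/2
            ([0, 1], [2, 3], 0.0),  # reversed separation
        ],
    )
    def test_auc_examples(self, pos, neg, auc):
        s, r = labelled(pos, neg)
        assert roc_curve(s, r).auc == pytest.approx(auc, abs=1e-12)

    def test_single_class_rejected(self):
        s = pd.Series({"a": 1.0, "b": 2.0})
        r = pd.Series({"a": True, "b": True})
        with pytest.raises(PredictionError, match="at least one"):
            roc_curve(s, r)

    def test_unmatched_ids_listed(self):
        s = pd.Series({"a": 1.0, "zz": 2.0, "b": 0.5})
        r = pd.Series({"a": True, "b": False})
        with pytest.raises(PredictionError, match="zz"):
            roc_curve(s, r)

    def test_thresholds_ordered_and_bracketing(self):
        s, r = labelled([1.0, 2.0], [0.0, 3.0])
        roc = roc_curve(s, r)
        assert (np.diff(roc.thresholds) > 0).all()
        assert roc.thresholds[0] < s.min() and roc.thresholds[-1] > s.max()
        assert ((0 <= roc.sensitivity) & (roc.sensitivity <= 1)).all()
        assert ((0 <= roc.specificity) & (roc.specificity <= 1)).all()


class TestSelectCutoff:
    @pytest.mark.parametrize(
        "pos, neg, cutoff, sens",
        [
            ([2, 3], [0, 1], 1.5, 1.0),  # midpoint of the separating gap
            ([1, 3], [2], 2.5, 0.5),
            ([0, 1], [2, 3], 4.0, 0.0),  # reversed: only the above-max sentinel
        ],
    )
    def test_full_specificity_selection(self, pos, neg, cutoff, sens):
        s, r = labelled(pos, neg)
        sel = select_cutoff(roc_curve(s, r), min_specificity=1.0)
        assert sel.cutoff == pytest.approx(cutoff)
        assert sel.sensitivity == pytest.approx(sens)
        assert sel.specificity == 1.0

    def test_relaxed_constraint_can_gain_sensitivity(self):
        s, r = labelled([1, 3, 4], [0, 2])
        strict = select_cutoff(roc_curve(s, r), min_specificity=1.0)
        relaxed = select_cutoff(roc_curve(s, r), min_specificity=0.5)
        assert relaxed.sensitivity >= strict.sensitivity
        assert relaxed.specificity >= 0.5


class TestApplyCutoff:
    def test_one_each_side(self):
        s, r = labelled([2.0], [0.0])
        conf = apply_cutoff(s, 1.0, r)
        assert (conf.tp, conf.fp, conf.tn, conf.fn) == (1, 0, 1, 0)

    def test_score_at_cutoff_is_predicted_responder(self):
        s, r = labelled([1.5], [0.0])
        conf = apply_cutoff(s, 1.5, r)
        assert conf.fn == 1 and conf.tp == 0
        conf_inc = apply_cutoff(s, 1.5, r, inclusive=True)
        assert conf_inc.tp == 1

    def test_separating_cutoff_counts(self):
        s, r = labelled([2, 3], [0, 1])
        conf = apply_cutoff(s, 1.5, r)
        assert (conf.tp, conf.fn, conf.tn, conf.fp) == (2, 0, 2, 0)


class TestRocOracles:
    """Implementation vs exhaustive independent oracles on random instances."""

    def random_instance(self, rng):
        n_pos = rng.integers(1, 7)
        n_neg = rng.integers(1, 12 - n_pos)
        # small integer grid provokes ties
        pos = rng.integers(0, 6, n_pos) + rng.choice([0.0, 0.5], n_pos)
        neg = rng.integers(0, 6, n_neg) + rng.choice([0.0, 0.5], n_neg)
        return pos, neg

    def test_auc_equals_pair_counting(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            pos, neg = self.random_instance(rng)
            s, r = labelled(pos, neg)
            auc = roc_curve(s, r).auc
            assert auc == pytest.approx(
                auc_by_pair_counting(pos, neg), abs=1e-12
            )

    def test_select_cutoff_matches_brute_force(self):
        rng = np.random.default_rng(43)
        for _ in range(300):
            pos, neg = self.random_instance(rng)
            min_spec = rng.choice([1.0, 0.9, 0.75, 0.5])
            s, r = labelled(pos, neg)
            sel = select_cutoff(roc_curve(s, r), min_specificity=min_spec)
            bf_sens, bf_spec, bf_cut = brute_force_cutoff(pos, neg, min_spec)
            assert sel.sensitivity == pytest.approx(bf_sens, abs=1e-12)
            assert sel.specificity == pytest.approx(bf_spec, abs=1e-12)
            assert sel.cutoff == pytest.approx(bf_cut, abs=1e-12)

    def test_sklearn_auc_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(44)
        for _ in range(50):
            pos = rng.normal(1, 1, rng.integers(2, 20))
            neg = rng.normal(0, 1, rng.integers(2, 20))
            s, r = labelled(pos, neg)
            y = (~r[s.index]).astype(int)
            assert roc_curve(s, r).auc == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )

    @settings(max_examples=40, deadline=None)
    @given(
        pos=st.lists(st.integers(-20, 20), min_size=1, max_size=6),
        neg=st.lists(st.integers(-20, 20), min_size=1, max_size=6),
        shift=st.floats(0.1, 3.0),
    )
    def test_monotone_invariance(self, pos, neg, shift):
        """AUC and the achieved operating point are invariant under a
        strictly increasing transform of all scores."""
        f = lambda v: np.exp(shift * np.asarray(v, dtype=float) / 20.0)
        s1, r = labelled(pos, neg)
        s2, _ = labelled(f(pos), f(neg))
        roc1, roc2 = roc_curve(s1, r), roc_curve(s2, r)
        assert roc1.auc == pytest.approx(roc2.auc, abs=1e-12)
        sel1 = select_cutoff(roc1)
        sel2 = select_cutoff(roc2)
        assert sel1.sensitivity == pytest.approx(sel2.sensitivity, abs=1e-12)
        assert sel1.specificity == pytest.approx(sel2.specificity, abs=1e-12)


def make_cohort(predn_flags, ids):
    return CohortTable(
        pd.DataFrame(
            {
                "patient_id": ids,
                "prednisone_use": predn_flags,
                "prednisone_dose_mg_day": [10.0 * f for f in predn_flags],
                "das28_baseline": [5.8] * len(ids),
                "das28_month6": [4.0] * len(ids),
            }
        )
    )


class TestStratifiedModel:
    def test_published_confusion_structure(self):
        """The printed cohort composition yields 41% unstratified, 88% in
        PREDN−, 29% in PREDN+ and 50% pooled sensitivity at 100%
        specificity."""
        scores, clinical = published_confusion_cohort()
        res = IfnResponseModel(scores, clinical).fit()
        assert as_percent(res.unstratified.cutoff.sensitivity) == 41
        assert as_percent(res.strata["PREDN-"].cutoff.sensitivity) == 88
        assert res.strata["PREDN-"].confusion.tp == 7
        assert res.strata["PREDN+"].confusion.tp == 4
        assert as_percent(res.overall_sensitivity) == 50
        assert res.overall_specificity == 1.0
        assert res.unstratified.confusion.tp == 9

    def test_single_stratum_equals_unstratified(self):
        scores, clinical = published_confusion_cohort()
        frame = clinical.frame.copy()
        frame["prednisone_use"] = True
        frame["prednisone_dose_mg_day"] = 5.0
        res = stratified_predict(scores, CohortTable(frame.reset_index()))
        (only,) = res.strata.values()
        assert only.cutoff.cutoff == res.unstratified.cutoff.cutoff
        assert only.confusion.to_dict() == res.unstratified.confusion.to_dict()

    def test_two_point_strata_beat_pooled(self):
        """Strata {r:0, nr:1} and {r:2, nr:3}: pooled sensitivity 1/2,
        stratified 2/2 at 100% specificity."""
        s = pd.Series({"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0})
        resp = pd.Series({"a": True, "b": False, "c": True, "d": False})
        cohort = make_cohort([0, 0, 1, 1], ["a", "b", "c", "d"])
        res = IfnResponseModel(s, cohort, labels=resp).fit()
        assert res.unstratified.confusion.tp == 1
        assert res.aggregate.tp == 2
        assert res.overall_specificity == 1.0

    def test_unevaluable_stratum_reported_not_merged(self):
        s = pd.Series({"a": 0.0, "b": 1.0, "c": 2.0})
        resp = pd.Series({"a": True, "b": False, "c": False})
        cohort = make_cohort([0, 0, 1], ["a", "b", "c"])
        res = IfnResponseModel(s, cohort, labels=resp).fit()
        assert not res.strata["PREDN+"].evaluable
        assert res.strata["PREDN-"].evaluable
        # aggregate covers only evaluable strata
        assert res.aggregate.n == 2

    def test_unknown_stratify_column_rejected(self):
        scores, clinical = published_confusion_cohort()
        with pytest.raises(PredictionError, match="nope"):
            IfnResponseModel(scores, clinical, stratify_by="nope")

    def test_report_json_keys_and_determinism(self, tmp_path):
        scores, clinical = published_confusion_cohort()
        res1 = IfnResponseModel(scores, clinical).fit()
        res2 = IfnResponseModel(scores, clinical).fit()
        assert res1.to_json() == res2.to_json()
        d = json.loads(res1.to_json())
        assert set(d) == {
            "aggregate",
            "min_specificity",
            "strata",
            "stratify_by",
            "unstratified",
        }
        inv = d["strata"]["PREDN-"]
        assert inv["confusion"]["tp"] + inv["confusion"]["fn"] == inv["n_non_responders"]
        assert inv["confusion"]["tn"] + inv["confusion"]["fp"] == inv["n_responders"]

    def test_stratified_tp_never_below_best_stratum(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(6, 16))
            ids = [f"p{i}" for i in range(n)]
            s = pd.Series(rng.normal(size=n), index=ids)
            resp = pd.Series(rng.random(n) < 0.5, index=ids)
            predn = rng.integers(0, 2, n)
            if resp.all() or (~resp).all():
                continue
            cohort = make_cohort(list(predn), ids)
            res = IfnResponseModel(s, cohort, labels=resp).fit()
            best = max(
                (st.confusion.tp for st in res.strata.values() if st.evaluable),
                default=0,
            )
            assert res.aggregate.tp >= best
            # confusion conservation per stratum and in aggregate
            for st_ in res.strata.values():
                if st_.evaluable:
                    assert st_.confusion.n == st_.n
            assert res.aggregate.n == sum(
                st_.n for st_ in res.strata.values() if st_.evaluable
            )


@pytest.mark.parametrize(
    "fraction, pct", [(7 / 8, 88), (9 / 22, 41), (5 / 8, 63), (0.5, 50), (0.625, 63)]
)
def test_percent_rounds_half_away_from_zero(fraction, pct):
    assert as_percent(fraction) == pct
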