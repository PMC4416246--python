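"""Rituximab non-response prediction from the IFN-score.

The positive state throughout is *non-response* (ΔDAS28 ≤ 1.2): a high
baseline IFN-score predicts a poor response to rituximab, so a sample is
called non-responder when its score exceeds the cut-off (strict ``>`` by
default; a flag switches to ``≥``).

The central procedure is specificity-constrained cut-off selection: among
all candidate thresholds (midpoints between consecutive distinct scores,
plus sentinels below the minimum and above the maximum), keep those whose
specificity meets the constraint (100% by default — no responder may be
misclassified) and pick the one with maximal sensitivity, breaking ties
toward higher specificity and then toward the larger threshold (the most
conservative call of non-response).  Because the above-maximum sentinel
always achieves specificity 1 at sensitivity 0, a feasible threshold always
exists.

The user-facing entry point is the statsmodels-style pair
:class:`IfnResponseModel` / :class:`IfnResponseResults`: the model is built
from a score table and a clinical cohort, ``fit()`` selects per-stratum
cut-offs (prednisone use by default) and returns a results object carrying
per-stratum ROC curves, cut-offs, confusion counts, the pooled aggregate and
the unstratified comparator, with ``summary()`` and JSON serialisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clinical import CohortTable, ResponseLabels, classify_response
from .errors import PredictionError
from .scoring import ScoreTable

UNSTRATIFIED = "unstratified"

#: Cut-offs printed for the original rituximab cohort live in
#: :mod:`ifnscore.examples`; they are data-derived constants, not defaults.


def as_percent(fraction: float) -> int:
    """Fraction → integer percent, rounding half away from zero (7/8 → 88)."""
    if math.isnan(fraction):
        raise PredictionError("cannot express NaN as a percentage")
    sign = -1 if fraction < 0 else 1
    return sign * int(math.floor(abs(fraction) * 100 + 0.5))


def _score_series(scores: ScoreTable | pd.Series | Mapping[str, float]) -> pd.Series:
    if isinstance(scores, ScoreTable):
        s = scores.scores
    else:
        s = pd.Series(scores, dtype=float)
    s.index = s.index.astype(str)
    return s.astype(float)


def _responder_series(labels: ResponseLabels | pd.Series | Mapping[str, bool]) -> pd.Series:
    if isinstance(labels, ResponseLabels):
        s = labels.responder
    else:
        s = pd.Series(labels)
    s.index = s.index.astype(str)
    return s.astype(bool)


def _align(scores, labels) -> tuple[pd.Series, pd.Series]:
    s = _score_series(scores)
    r = _responder_series(labels)
    unmatched = [i for i in s.index if i not in r.index]
    if unmatched:
        shown = ", ".join(unmatched[:10])
        more = "" if len(unmatched) <= 10 else f" (+{len(unmatched) - 10} more)"
        raise PredictionError(f"scored sample(s) without response label: {shown}{more}")
    r = r[s.index]
    return s, r


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted scores, plus one
    sentinel below the minimum and one above the maximum."""
    v = np.unique(np.asarray(values, dtype=float))
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[v[0] - 1.0], mids, [v[-1] + 1.0]])


@dataclass
class RocCurve:
    """Empirical ROC for non-response prediction (positive = non-responder,
    predicted positive when score > threshold)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_positive: int
    n_negative: int

    @property
    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_curve(
    scores: ScoreTable | pd.Series,
    labels: ResponseLabels | pd.Series,
    inclusive: bool = False,
) -> RocCurve:
    """Empirical ROC over all candidate thresholds.

    AUC is the trapezoidal area over (1 − specificity, sensitivity), which
    for this construction equals the concordance probability
    (#concordant + ½·#tied) / (n₊ · n₋).
    """
    s, r = _align(scores, labels)
    pos = (~r).to_numpy()  # non-responders
    x = s.to_numpy()
    n_pos = int(pos.sum())
    n_neg = int(len(pos) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise PredictionError(
            "ROC needs at least one responder and one non-responder "
            f"(got {n_neg} responders, {n_pos} non-responders)"
        )
    thr = candidate_thresholds(x)
    if inclusive:
        pred = x[None, :] >= thr[:, None]
    else:
        pred = x[None, :] > thr[:, None]
    tp = (pred & pos[None, :]).sum(axis=1)
    fp = (pred & ~pos[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    fpr = fp / n_neg
    # thresholds ascend, so fpr descends from 1 to 0; integrate |dx|
    auc = float(abs(np.trapezoid(sens, fpr)))
    return RocCurve(thr, sens, spec, auc, n_pos, n_neg)


@dataclass
class CutoffSelection:
    cutoff: float
    sensitivity: float
    specificity: float
    constraint: float  # minimum specificity demanded


def select_cutoff(roc: RocCurve, min_specificity: float = 1.0) -> CutoffSelection:
    """Maximal-sensitivity threshold subject to specificity ≥ constraint.

    Ties on sensitivity break toward higher specificity, then toward the
    larger threshold.
    """
    if not 0 <= min_specificity <= 1:
        raise PredictionError("min_specificity must be in [0, 1]")
    ok = roc.specificity >= min_specificity - 1e-12
    if not ok.any():  # unreachable: the above-maximum sentinel qualifies
        raise PredictionError("no threshold satisfies the specificity constraint")
    idx = np.flatnonzero(ok)
    order = np.lexsort(
        (roc.thresholds[idx], roc.specificity[idx], roc.sensitivity[idx])
    )
    best = idx[order[-1]]
    return CutoffSelection(
        float(roc.thresholds[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
        float(min_specificity),
    )


@dataclass
class ConfusionCounts:
    """2×2 confusion cells with positive = non-responder."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def correct_fraction(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else math.nan

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    def to_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def apply_cutoff(
    scores: ScoreTable | pd.Series,
    cutoff: float,
    labels: ResponseLabels | pd.Series,
    inclusive: bool = False,
) -> ConfusionCounts:
    """Confusion counts of the rule 'score > cutoff ⇒ predicted non-responder'.

    A score exactly at the cut-off is predicted responder (strict
    inequality); ``inclusive=True`` flips that boundary.
    """
    s, r = _align(scores, labels)
    pos = (~r).to_numpy()
    pred = (s.to_numpy() >= cutoff) if inclusive else (s.to_numpy() > cutoff)
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


# ---------------------------------------------------------------------------
# Stratified model / results
# ---------------------------------------------------------------------------


@dataclass
class StratumResult:
    name: str
    n: int
    n_responders: int
    n_non_responders: int
    evaluable: bool
    roc: RocCurve | None = None
    cutoff: CutoffSelection | None = None
    confusion: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "n": self.n,
            "n_responders": self.n_responders,
            "n_non_responders": self.n_non_responders,
            "evaluable": self.evaluable,
        }
        if self.evaluable:
            d.update(
                auc=self.roc.auc,
                cutoff=self.cutoff.cutoff,
                sensitivity=self.cutoff.sensitivity,
                specificity=self.cutoff.specificity,
                sensitivity_pct=as_percent(self.cutoff.sensitivity),
                specificity_pct=as_percent(self.cutoff.specificity),
                confusion=self.confusion.to_dict(),
                correct_fraction=self.confusion.correct_fraction,
            )
        return d


@dataclass
class IfnResponseResults:
    """Fitted stratified cut-off report.

    Carries, per stratum, the ROC curve, the selected cut-off and its
    confusion counts; the pooled aggregate over evaluable strata; and the
    unstratified analysis for comparison.
    """

    strata: dict[str, StratumResult]
    unstratified: StratumResult
    aggregate: ConfusionCounts
    min_specificity: float
    stratify_by: str

    @property
    def overall_sensitivity(self) -> float:
        return self.aggregate.sensitivity

    @property
    def overall_specificity(self) -> float:
        return self.aggregate.specificity

    def to_dict(self) -> dict:
        return {
            "stratify_by": self.stratify_by,
            "min_specificity": self.min_specificity,
            "strata": {k: v.to_dict() for k, v in self.strata.items()},
            "unstratified": self.unstratified.to_dict(),
            "aggregate": {
                "confusion": self.aggregate.to_dict(),
                "sensitivity": self.overall_sensitivity,
                "specificity": self.overall_specificity,
                "sensitivity_pct": as_percent(self.overall_sensitivity),
                "specificity_pct": as_percent(self.overall_specificity),
                "correct_fraction": self.aggregate.correct_fraction,
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def roc_points(self) -> pd.DataFrame:
        """ROC points of every evaluable stratum plus the unstratified
        analysis, long format, for CSV export / plotting."""
        frames = []
        for name, st in {**self.strata, UNSTRATIFIED: self.unstratified}.items():
            if st.evaluable:
                pts = st.roc.points.copy()
                pts.insert(0, "stratum", name)
                frames.append(pts)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = [
            "IFN-score non-response prediction "
            f"(stratified by {self.stratify_by}, min specificity "
            f"{self.min_specificity:g})",
            "",
            f"{'stratum':<14}{'n':>4}{'resp':>6}{'nonresp':>8}{'AUC':>8}"
            f"{'cutoff':>9}{'sens':>7}{'spec':>7}",
        ]
        rows = list(self.strata.items()) + [(UNSTRATIFIED, self.unstratified)]
        for name, st in rows:
            if st.evaluable:
                lines.append(
                    f"{name:<14}{st.n:>4}{st.n_responders:>6}"
                    f"{st.n_non_responders:>8}{st.roc.auc:>8.3f}"
                    f"{st.cutoff.cutoff:>9.3f}"
                    f"{as_percent(st.cutoff.sensitivity):>6d}%"
                    f"{as_percent(st.cutoff.specificity):>6d}%"
                )
            else:
                lines.append(
                    f"{name:<14}{st.n:>4}{st.n_responders:>6}"
                    f"{st.n_non_responders:>8}{'--':>8}{'--':>9}"
                    f"{'--':>7}{'--':>7}  (unevaluable)"
                )
        agg = self.aggregate
        lines += [
            "",
            f"aggregate (evaluable strata): TP={agg.tp} FP={agg.fp} "
            f"TN={agg.tn} FN={agg.fn}",
            f"overall sensitivity {as_percent(agg.sensitivity)}% "
            f"({agg.tp}/{agg.tp + agg.fn}), "
            f"overall specificity {as_percent(agg.specificity)}% "
            f"({agg.tn}/{agg.tn + agg.fp})",
        ]
        return "\n".join(lines)


class IfnResponseModel:
    """Prednisone-stratified, specificity-constrained cut-off model.

    Parameters
    ----------
    scores
        Per-sample IFN-scores (ScoreTable or Series indexed by patient id).
    cohort
        Clinical table; supplies the stratification column and, when
        ``labels`` is None, the DAS28 values from which responder labels are
        derived (ΔDAS28 > 1.2).
    labels
        Optional precomputed responder labels.
    stratify_by
        Clinical column defining the strata (default ``prednisone_use``,
        rendered as PREDN+ / PREDN−).
    min_specificity
        Specificity constraint for cut-off selection (default 1.0: no
        responder may be called a non-responder).
    inclusive
        Use ``score ≥ cutoff`` instead of strict ``>`` for the positive call.
    """

    def __init__(
        self,
        scores: ScoreTable | pd.Series,
        cohort: CohortTable,
        labels: ResponseLabels | pd.Series | None = None,
        stratify_by: str = "prednisone_use",
        min_specificity: float = 1.0,
        inclusive: bool = False,
    ) -> None:
        self.scores = _score_series(scores)
        self.cohort = cohort
        if stratify_by not in cohort.frame.columns:
            raise PredictionError(
                f"unknown stratification column {stratify_by!r}; "
                f"clinical columns: {list(cohort.frame.columns)}"
            )
        self.stratify_by = stratify_by
        self.min_specificity = float(min_specificity)
        self.inclusive = bool(inclusive)
        not_in_clinical = [
            i for i in self.scores.index if i not in cohort.frame.index
        ]
        if not_in_clinical:
            shown = ", ".join(not_in_clinical[:10])
            more = (
                "" if len(not_in_clinical) <= 10
                else f" (+{len(not_in_clinical) - 10} more)"
            )
            raise PredictionError(
                f"scored sample(s) missing from the clinical table: {shown}{more}"
            )
        if labels is None:
            labels = classify_response(cohort)
        self.labels = labels
        resp = _responder_series(labels)
        # analysis set: scored AND labelled (unlabelled = missing month-6 DAS28)
        ids = [i for i in self.scores.index if i in resp.index]
        if not ids:
            raise PredictionError("no patient has both a score and a response label")
        self._ids = ids

    @classmethod
    def from_dataframes(
        cls,
        score_frame: pd.DataFrame,
        clinical_frame: pd.DataFrame,
        score_column: str = "ifn_score",
        **kwargs,
    ) -> "IfnResponseModel":
        """Build from raw DataFrames (score table with ``sample_id`` /
        ``patient_id`` index or column, clinical table as documented in
        :class:`~ifnscore.clinical.CohortTable`)."""
        sf = score_frame
        if sf.index.name not in ("sample_id", "patient_id"):
            for c in ("sample_id", "patient_id"):
                if c in sf.columns:
                    sf = sf.set_index(c)
                    break
        scores = sf[score_column]
        return cls(scores, CohortTable(clinical_frame), **kwargs)

    def _stratum_name(self, value: object) -> str:
        if self.stratify_by == "prednisone_use":
            return "PREDN+" if bool(value) else "PREDN-"
        return str(value)

    def _fit_block(self, name: str, ids: list[str]) -> StratumResult:
        resp = _responder_series(self.labels)[ids]
        s = self.scores[ids]
        n_resp = int(resp.sum())
        n_nonresp = int((~resp).sum())
        if n_resp == 0 or n_nonresp == 0:
            return StratumResult(name, len(ids), n_resp, n_nonresp, evaluable=False)
        roc = roc_curve(s, resp, inclusive=self.inclusive)
        sel = select_cutoff(roc, self.min_specificity)
        conf = apply_cutoff(s, sel.cutoff, resp, inclusive=self.inclusive)
        return StratumResult(
            name, len(ids), n_resp, n_nonresp, True, roc, sel, conf
        )

    def fit(self) -> IfnResponseResults:
        """Select per-stratum cut-offs and assemble the stratified report."""
        col = self.cohort.frame[self.stratify_by]
        groups: dict[str, list[str]] = {}
        for pid in self._ids:
            groups.setdefault(self._stratum_name(col[pid]), []).append(pid)
        strata = {
            name: self._fit_block(name, ids) for name, ids in sorted(groups.items())
        }
        unstrat = self._fit_block(UNSTRATIFIED, self._ids)
        agg = ConfusionCounts(0, 0, 0, 0)
        for st in strata.values():
            if st.evaluable:
                agg = agg + st.confusion
        return IfnResponseResults(
            strata, unstrat, agg, self.min_specificity, self.stratify_by
        )


def stratified_predict(
    scores: ScoreTable | pd.Series,
    cohort: CohortTable,
    labels: ResponseLabels | pd.Series | None = None,
    stratify_by: str = "prednisone_use",
    min_specificity: float = 1.0,
    inclusive: bool = False,
) -> IfnResponseResults:
    """One-shot functional wrapper around :class:`IfnResponseModel`."""
    return IfnResponseModel(
        scores, cohort, labels, stratify_by, min_specificity, inclusive
    ).fit()
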