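"""Clinical records, response labelling and group-comparison statistics.

The clinical table carries, per patient: current prednisone use and dose
(mg/day), DAS28 at baseline and at month 6 of rituximab therapy, and any
extra covariates (carried opaquely).  Response to rituximab is the EULAR-style
rule ΔDAS28 = baseline − month6 > 1.2 (strict).

Group comparisons mirror common biomarker practice: a normality-gated choice
between Student's unpaired t-test and the Mann-Whitney rank-sum test for two
groups, and Kruskal-Wallis across prednisone dose bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ClinicalError
from .scoring import ScoreTable

RESPONSE_DELTA = 1.2  # ΔDAS28 threshold defining a responder (strict >)
# DAS28 is reported to ~1 decimal; differences within float noise of the
# threshold count as equal so that e.g. 5.0 − 3.8 is NOT a response
_DELTA_EPS = 1e-9

REQUIRED_COLUMNS = (
    "patient_id",
    "prednisone_use",
    "prednisone_dose_mg_day",
    "das28_baseline",
    "das28_month6",
)


@dataclass
class CohortTable:
    """Per-patient clinical table with validated core columns.

    ``frame`` is indexed by patient_id and keeps extra covariate columns
    untouched.  Invariants enforced: unique patient ids, dose ≥ 0, dose 0 for
    non-users, DAS28 values within [0, 10] (month-6 may be missing).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.name != "patient_id":
            if "patient_id" not in df.columns:
                raise ClinicalError("missing required column: patient_id")
            df = df.set_index("patient_id")
        df.index = df.index.astype(str)
        for col in REQUIRED_COLUMNS[1:]:
            if col not in df.columns:
                raise ClinicalError(f"missing required column: {col}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ClinicalError(f"duplicate patient id(s): {dups[:10]}")
        use = df["prednisone_use"]
        if not use.isin([0, 1, True, False]).all():
            raise ClinicalError("prednisone_use must be boolean (0/1)")
        df["prednisone_use"] = use.astype(bool)
        dose = pd.to_numeric(df["prednisone_dose_mg_day"], errors="coerce")
        if dose.isna().any() or (dose < 0).any():
            raise ClinicalError("prednisone_dose_mg_day must be numeric and ≥ 0")
        df["prednisone_dose_mg_day"] = dose.astype(float)
        bad = df.index[(~df["prednisone_use"]) & (dose != 0)].tolist()
        if bad:
            raise ClinicalError(
                f"non-zero prednisone dose for non-user(s): {bad[:10]}"
            )
        for col in ("das28_baseline", "das28_month6"):
            v = pd.to_numeric(df[col], errors="coerce")
            given = df[col].notna()
            if (v[given].isna()).any():
                raise ClinicalError(f"{col} contains non-numeric values")
            if ((v < 0) | (v > 10)).any():
                raise ClinicalError(f"{col} outside the DAS28 range [0, 10]")
            df[col] = v.astype(float)
        self.frame = df

    @property
    def patient_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, dtype={"patient_id": str})
        return cls(df)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.frame.copy()
        out["prednisone_use"] = out["prednisone_use"].astype(int)
        out.to_csv(path)
        return path


@dataclass
class ResponseLabels:
    """ΔDAS28-derived responder labels.

    ``frame``: indexed by patient_id, columns ``delta_das28`` and
    ``responder`` (bool); ``excluded``: ids without a month-6 DAS28.
    """

    frame: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    @property
    def responder(self) -> pd.Series:
        return self.frame["responder"]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


def classify_response(cohort: CohortTable) -> ResponseLabels:
    """Label responders by ΔDAS28 = baseline − month6 > 1.2 (strict).

    Patients with a missing month-6 DAS28 cannot be labelled; they are
    excluded and listed in ``excluded``.
    """
    df = cohort.frame
    has = df["das28_month6"].notna()
    delta = df.loc[has, "das28_baseline"] - df.loc[has, "das28_month6"]
    out = pd.DataFrame(
        {"delta_das28": delta, "responder": delta > RESPONSE_DELTA + _DELTA_EPS}
    )
    out.index.name = "patient_id"
    return ResponseLabels(out, excluded=list(df.index[~has]))


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

T_UNPAIRED = "t_unpaired"
RANK_SUM = "rank_sum"
KRUSKAL_WALLIS = "kruskal_wallis"


@dataclass
class GroupTestResult:
    test_name: str
    statistic: float
    p_value: float
    group_summaries: dict[str, dict[str, float]]
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_summaries": self.group_summaries,
            "details": self.details,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _summary(x: np.ndarray) -> dict[str, float]:
    return {
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
    }


def _score_series(scores: ScoreTable | pd.Series | Mapping[str, float]) -> pd.Series:
    if isinstance(scores, ScoreTable):
        return scores.scores
    return pd.Series(scores, dtype=float)


def compare_score_by_group(
    scores: ScoreTable | pd.Series,
    groups: pd.Series | Mapping[str, object],
    policy: str = "auto",
    alpha_normality: float = 0.05,
) -> GroupTestResult:
    """Two-group comparison of IFN-scores with a normality-gated test choice.

    ``groups`` maps sample id → group label (exactly two levels).  Under
    ``policy="auto"`` the parametric branch (Student's unpaired t-test) is
    taken only when both groups pass Shapiro-Wilk at ``alpha_normality`` and
    each has n ≥ 8; otherwise a two-sided Mann-Whitney rank-sum test is run
    (exact enumeration when both n ≤ 10 and no ties, tie-corrected normal
    approximation otherwise).  ``force_t`` / ``force_rank`` bypass the gate.
    """
    if policy not in ("auto", "force_t", "force_rank"):
        raise ClinicalError(f"unknown policy {policy!r}")
    s = _score_series(scores)
    g = pd.Series(groups)
    g.index = g.index.astype(str)
    common = s.index.intersection(g.index)
    if len(common) == 0:
        raise ClinicalError("no overlap between scored samples and group labels")
    s, g = s[common], g[common]
    levels = sorted(pd.unique(g), key=str)
    if len(levels) != 2:
        raise ClinicalError(f"expected exactly 2 group levels, found {len(levels)}")
    x = s[g == levels[0]].to_numpy(dtype=float)
    y = s[g == levels[1]].to_numpy(dtype=float)
    for label, arr in zip(levels, (x, y)):
        if len(arr) < 2:
            raise ClinicalError(f"group {label!r} has fewer than 2 observations")

    details: dict = {"policy": policy, "group_order": [str(l) for l in levels]}
    use_t = False
    if policy == "force_t":
        use_t = True
    elif policy == "auto":
        if len(x) >= 8 and len(y) >= 8 and np.std(x) > 0 and np.std(y) > 0:
            px = stats.shapiro(x).pvalue
            py = stats.shapiro(y).pvalue
            details["shapiro_p"] = [float(px), float(py)]
            use_t = px > alpha_normality and py > alpha_normality
        else:
            details["normality_gate"] = "group n < 8 or zero variance; rank-sum used"

    if use_t:
        if np.std(x) == 0 or np.std(y) == 0:
            raise ClinicalError("zero within-group variance: t-test not defined")
        res = stats.ttest_ind(x, y, equal_var=True)
        name, stat, p = T_UNPAIRED, float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([x, y])
        ties = len(np.unique(pooled)) < len(pooled)
        if len(x) <= 10 and len(y) <= 10 and not ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        )
        name, stat, p = RANK_SUM, float(res.statistic), float(res.pvalue)
        details["rank_sum_method"] = method

    return GroupTestResult(
        name,
        stat,
        min(p, 1.0),
        {str(levels[0]): _summary(x), str(levels[1]): _summary(y)},
        details,
    )


#: Default prednisone dose bins (mg/day): non-users, (0, 5], (5, 10), [10, ∞).
#: Each bin is (label, low, high, closed) with closed ∈ {both, left, right, neither};
#: the open-ended top bin reflects suppression being strongest at ≥ 10 mg/day.
DEFAULT_DOSE_BINS: tuple[tuple[str, float, float, str], ...] = (
    ("0", 0.0, 0.0, "both"),
    ("0-5", 0.0, 5.0, "right"),
    ("5-10", 5.0, 10.0, "neither"),
    (">=10", 10.0, math.inf, "left"),
)


def assign_dose_bin(
    dose: float, bins: Sequence[tuple[str, float, float, str]] = DEFAULT_DOSE_BINS
) -> str | None:
    for label, lo, hi, closed in bins:
        lo_ok = dose >= lo if closed in ("both", "left") else dose > lo
        hi_ok = dose <= hi if closed in ("both", "right") else dose < hi
        if lo_ok and hi_ok:
            return label
    return None


def compare_dose_groups(
    scores: ScoreTable | pd.Series,
    cohort: CohortTable,
    bins: Sequence[tuple[str, float, float, str]] = DEFAULT_DOSE_BINS,
) -> GroupTestResult:
    """Kruskal-Wallis comparison of IFN-scores across prednisone dose bins.

    Tie-corrected H across all non-empty bins; fails if fewer than two bins
    are populated.
    """
    s = _score_series(scores)
    common = s.index.intersection(cohort.frame.index)
    if len(common) == 0:
        raise ClinicalError("no overlap between scored samples and cohort patients")
    dose = cohort.frame.loc[common, "prednisone_dose_mg_day"]
    grouped: dict[str, list[float]] = {}
    unassigned: list[str] = []
    for pid in common:
        label = assign_dose_bin(float(dose[pid]), bins)
        if label is None:
            unassigned.append(pid)
            continue
        grouped.setdefault(label, []).append(float(s[pid]))
    nonempty = [(lbl, np.asarray(v)) for lbl, v in grouped.items() if len(v) > 0]
    if len(nonempty) < 2:
        raise ClinicalError(
            f"Kruskal-Wallis needs ≥ 2 non-empty dose bins, found {len(nonempty)}"
        )
    order = [b[0] for b in bins if b[0] in dict(nonempty)]
    arrays = [dict(nonempty)[lbl] for lbl in order]
    res = stats.kruskal(*arrays)
    return GroupTestResult(
        KRUSKAL_WALLIS,
        float(res.statistic),
        float(res.pvalue),
        {lbl: _summary(arr) for lbl, arr in zip(order, arrays)},
        {"bins": order, "unassigned": unassigned},
    )


# ---------------------------------------------------------------------------
# Odds ratio
# ---------------------------------------------------------------------------


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied because of a zero cell

    def astuple(self) -> tuple[float, float, float]:
        return (self.odds_ratio, self.ci_low, self.ci_high)


def odds_ratio(table: Sequence[Sequence[float]] | np.ndarray) -> OddsRatioResult:
    """Cross-product odds ratio of a 2×2 count table with a Woolf 95% CI.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), flagged in the result.  CI: exp(log OR ± 1.96 · SE) with
    SE = sqrt(Σ 1/cell).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ClinicalError(f"expected a 2×2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ClinicalError("negative cell count")
    if not np.allclose(t, np.round(t)):
        raise ClinicalError("cell counts must be integers")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ClinicalError("zero row or column: odds ratio undefined")
    (a, b), (c, d) = t
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    return OddsRatioResult(float(or_), float(lo), float(hi), corrected)
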