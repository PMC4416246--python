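import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ifnscore import (
    CohortTable,
    ExpressionMatrix,
    ScoreTable,
    SimulationConfig,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, log2 scale, one missing cell."""
    data = pd.DataFrame(
        [[0.0, 1.0, 3.0, 10.0], [1.0, 2.0, 3.0, 4.0], [np.nan, 0.0, 0.0, 2.0]],
        index=["EPSTI1", "MX1", "RSAD2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data, {s: "qpcr" for s in data.columns})


@pytest.fixture
def irg8_matrix() -> ExpressionMatrix:
    """All 8 IRG8 genes, 2 samples with simple values."""
    genes = ["EPSTI1", "HERC5", "IFI44L", "ISG15", "LY6E", "MX1", "MX2", "RSAD2"]
    data = pd.DataFrame(
        {"a": [0.0] * 8, "b": [1, 2, 3, 4, 5, 6, 7, 8]}, index=genes, dtype=float
    )
    return ExpressionMatrix(data, {"a": "microarray", "b": "microarray"})


@pytest.fixture
def small_cohort() -> CohortTable:
    return CohortTable(
        pd.DataFrame(
            {
                "patient_id": ["p1", "p2", "p3", "p4"],
                "prednisone_use": [0, 1, 0, 1],
                "prednisone_dose_mg_day": [0.0, 10.0, 0.0, 5.0],
                "das28_baseline": [5.8, 5.0, 4.0, 6.5],
                "das28_month6": [4.0, 3.8, 4.5, None],
            }
        )
    )


@pytest.fixture
def fast_config() -> SimulationConfig:
    return SimulationConfig(n=50, seed=7)


def score_table(mapping) -> ScoreTable:
    return ScoreTable.from_scores(pd.Series(mapping, dtype=float))


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; kept free of the library's ROC code)
# ---------------------------------------------------------------------------


def auc_by_pair_counting(pos_scores, neg_scores) -> float:
    """Concordance probability by exhaustive pair enumeration."""
    conc = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                conc += 1.0
            elif p == q:
                conc += 0.5
    return conc / (len(pos_scores) * len(neg_scores))


def brute_force_cutoff(pos_scores, neg_scores, min_specificity=1.0):
    """Scan every candidate threshold with direct counting; return
    (cutoff, sensitivity, specificity) under the max-sensitivity /
    higher-specificity / larger-threshold tie-break."""
    import numpy as np

    values = np.unique(np.concatenate([pos_scores, neg_scores]).astype(float))
    cands = [values[0] - 1.0]
    cands += [(a + b) / 2.0 for a, b in zip(values[:-1], values[1:])]
    cands += [values[-1] + 1.0]
    best = None
    for t in cands:
        sens = sum(1 for p in pos_scores if p > t) / len(pos_scores)
        spec = sum(1 for q in neg_scores if q <= t) / len(neg_scores)
        if spec < min_specificity - 1e-12:
            continue
        key = (sens, spec, t)
        if best is None or key > best:
            best = key
    return best
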