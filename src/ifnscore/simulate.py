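"""Synthetic rituximab-cohort generator.

Generates seeded cohorts with the statistical structure the analysis
assumes, so every pipeline stage can be exercised without patient data:

* a *bimodal* genuine IFN-score — a two-component Gaussian mixture, the
  IFN-high class present in ~50% of patients;
* *dose-dependent suppression* of the observed score in prednisone users,
  saturating with dose by default (δ(d) = delta_max · d / (d + d50));
* response driven by the *latent* class, not the observed score: an
  IFN-high patient suppressed into the low range remains a likely
  non-responder, which is exactly the mechanism that degrades prediction in
  prednisone users;
* gene-level log2 values scattered around the (suppressed) score mean, so
  the scoring stage has real work to do;
* DAS28 baseline / month-6 pairs realised to be consistent with the drawn
  responder label (they carry no extra information — the pipeline consumes
  them only through the ΔDAS28 > 1.2 rule).

All randomness flows from a single integer seed; identical configs and
seeds give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .clinical import CohortTable, RESPONSE_DELTA
from .errors import ConfigError
from .expression import ExpressionMatrix, QPCR, write_expression_table
from .scoring import IRG8, ScoreTable

LINEAR = "linear"
SATURATING = "saturating"

# DAS28 at baseline in the rituximab cohort: 5.8 ± 1.1, truncated to the
# high-disease-activity entry window [3.2, 10].
_DAS28_MEAN = 5.8
_DAS28_SD = 1.1
_DAS28_LO = 3.2
_DAS28_HI = 10.0
# scale of the |ΔDAS28 − 1.2| margin used to realise responder labels
_DELTA_SCALE = 0.8


def _default_doses() -> tuple[tuple[float, float], ...]:
    doses = (2.5, 5.0, 7.5, 10.0, 15.0, 20.0)
    return tuple((d, 1.0 / len(doses)) for d in doses)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Defaults encode the study-like conditions: ~50% IFN-high prevalence,
    prednisone use in 67.5% of patients (27/40 in the rituximab cohort),
    daily doses uniform over 2.5–20 mg, saturating suppression, and response
    probabilities 0.2 / 0.8 given the IFN-high / IFN-low latent class.
    """

    n: int = 200
    seed: int = 0
    p_prednisone: float = 0.675
    dose_choices: tuple[tuple[float, float], ...] = field(
        default_factory=_default_doses
    )
    p_ifn_high: float = 0.5
    mu_low: float = 0.0
    mu_high: float = 1.5
    sigma_score: float = 0.4
    suppression: str = SATURATING
    delta_max: float = 1.2  # log2 units, asymptotic suppression
    d50: float = 5.0  # mg/day at half-maximal suppression (saturating)
    slope: float = 0.06  # log2 units per mg/day (linear)
    p_respond_given_high: float = 0.2
    p_respond_given_low: float = 0.8
    n_genes: int = 8
    sigma_gene: float = 0.3
    gene_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        def bad(name: str, why: str = "") -> ConfigError:
            return ConfigError(f"invalid SimulationConfig field {name!r}{why}")

        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise bad("n", ": must be a positive integer")
        if not isinstance(self.seed, (int, np.integer)):
            raise bad("seed", ": must be an integer")
        for name in (
            "p_prednisone",
            "p_ifn_high",
            "p_respond_given_high",
            "p_respond_given_low",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise bad(name, ": probability must be in [0, 1]")
        for name in ("sigma_score", "sigma_gene", "delta_max"):
            if getattr(self, name) < 0:
                raise bad(name, ": must be ≥ 0")
        if not self.mu_high > self.mu_low:
            raise bad("mu_high", ": must exceed mu_low")
        if self.suppression not in (LINEAR, SATURATING):
            raise bad("suppression", f": must be {LINEAR!r} or {SATURATING!r}")
        if self.suppression == SATURATING and self.d50 <= 0:
            raise bad("d50", ": must be > 0")
        if self.n_genes < 1:
            raise bad("n_genes", ": must be ≥ 1")
        if not self.dose_choices:
            raise bad("dose_choices", ": must be non-empty")
        doses, probs = zip(*self.dose_choices)
        if any(d < 0 for d in doses):
            raise bad("dose_choices", ": doses must be ≥ 0")
        if any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise bad("dose_choices", ": probabilities must be ≥ 0 and sum to 1")
        if self.gene_offsets is not None and len(self.gene_offsets) != self.n_genes:
            raise bad("gene_offsets", f": must have length n_genes={self.n_genes}")

    # -- gene symbols ------------------------------------------------------
    @property
    def gene_symbols(self) -> tuple[str, ...]:
        base = IRG8.genes
        if self.n_genes <= len(base):
            return base[: self.n_genes]
        extra = tuple(f"SYNIRG{i}" for i in range(1, self.n_genes - len(base) + 1))
        return base + extra

    @property
    def offsets(self) -> np.ndarray:
        if self.gene_offsets is None:
            return np.zeros(self.n_genes)
        return np.asarray(self.gene_offsets, dtype=float)

    def delta(self, dose: np.ndarray | float) -> np.ndarray | float:
        """Mean suppression δ(dose) in log2 units for a prednisone user."""
        d = np.asarray(dose, dtype=float)
        if self.suppression == SATURATING:
            out = np.where(d > 0, self.delta_max * d / (d + self.d50), 0.0)
        else:
            out = np.minimum(self.slope * d, self.delta_max)
        return out if out.shape else float(out)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["dose_choices"] = [list(pair) for pair in self.dose_choices]
        if self.gene_offsets is not None:
            d["gene_offsets"] = list(self.gene_offsets)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown SimulationConfig field(s): {sorted(unknown)}")
        if "dose_choices" in d:
            d["dose_choices"] = tuple(tuple(map(float, p)) for p in d["dose_choices"])
        if d.get("gene_offsets") is not None:
            d["gene_offsets"] = tuple(map(float, d["gene_offsets"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of config fields")
        return cls.from_dict(data)


@dataclass
class SimulatedCohort:
    """Realised cohort: expression matrix, clinical table and latent truth.

    ``truth`` is indexed by patient id with columns ``latent_class``
    (IFN-high / IFN-low), ``genuine_score``, ``observed_score_expected``
    (= genuine − δ(dose) for users), ``dose`` and ``responder``.
    """

    config: SimulationConfig
    expression: ExpressionMatrix
    clinical: CohortTable
    truth: pd.DataFrame


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort from the generative model (deterministic in cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    ids = [f"P{i:04d}" for i in range(1, n + 1)]

    high = rng.random(n) < cfg.p_ifn_high
    genuine = rng.normal(np.where(high, cfg.mu_high, cfg.mu_low), cfg.sigma_score)
    predn = rng.random(n) < cfg.p_prednisone
    doses, probs = map(np.asarray, zip(*cfg.dose_choices))
    dose = rng.choice(doses, size=n, p=probs / probs.sum()) * predn
    observed = genuine - np.asarray(cfg.delta(dose)) * predn

    genes = observed[None, :] + cfg.offsets[:, None] + rng.normal(
        0.0, cfg.sigma_gene, size=(cfg.n_genes, n)
    )

    p_resp = np.where(high, cfg.p_respond_given_high, cfg.p_respond_given_low)
    responder = rng.random(n) < p_resp

    a = (_DAS28_LO - _DAS28_MEAN) / _DAS28_SD
    b = (_DAS28_HI - _DAS28_MEAN) / _DAS28_SD
    baseline = stats.truncnorm.rvs(
        a, b, loc=_DAS28_MEAN, scale=_DAS28_SD, size=n, random_state=rng
    )
    # floor keeps realised ΔDAS28 clear of the 1.2 boundary at float precision
    margin = 1e-3 + rng.exponential(_DELTA_SCALE, size=n)
    # realise ΔDAS28 strictly above 1.2 for responders, at or below otherwise;
    # clips keep month-6 DAS28 inside [0, 10] without crossing the 1.2 rule
    delta_das = np.where(responder, RESPONSE_DELTA + margin, RESPONSE_DELTA - margin)
    delta_das = np.where(responder, np.minimum(delta_das, baseline), delta_das)
    delta_das = np.where(
        ~responder, np.maximum(delta_das, baseline - _DAS28_HI), delta_das
    )
    month6 = baseline - delta_das

    expr = ExpressionMatrix(
        pd.DataFrame(genes, index=list(cfg.gene_symbols), columns=ids),
        {s: QPCR for s in ids},
        centered=False,
    )
    clinical = CohortTable(
        pd.DataFrame(
            {
                "patient_id": ids,
                "prednisone_use": predn.astype(int),
                "prednisone_dose_mg_day": dose,
                "das28_baseline": np.round(baseline, 6),
                "das28_month6": np.round(month6, 6),
            }
        )
    )
    truth = pd.DataFrame(
        {
            "latent_class": np.where(high, "IFN-high", "IFN-low"),
            "genuine_score": genuine,
            "observed_score_expected": observed,
            "dose": dose,
            "responder": responder,
        },
        index=pd.Index(ids, name="patient_id"),
    )
    return SimulatedCohort(cfg, expr, clinical, truth)


def write_cohort(
    cohort: SimulatedCohort, outdir: str | Path, provenance: bool = False
) -> dict[str, Path]:
    """Write the cohort trio: expression.tsv, clinical.csv, truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.csv",
    }
    write_expression_table(cohort.expression, paths["expression"], provenance=provenance)
    cohort.clinical.to_csv(paths["clinical"])
    cohort.truth.to_csv(paths["truth"], float_format="%.10g")
    return paths


@dataclass
class SuppressionEstimate:
    """Mean score suppression in prednisone users, with its standard error."""

    estimate: float  # mean(score | PREDN−) − mean(score | PREDN+), log2 units
    se: float
    n_nonusers: int
    n_users: int


def recover_suppression(
    cohort: SimulatedCohort | CohortTable, scores: ScoreTable | pd.Series
) -> SuppressionEstimate:
    """Estimate mean suppression as the PREDN− minus PREDN+ score difference.

    The standard error uses the pooled two-sample formula
    ``s_p · sqrt(1/n₋ + 1/n₊)``.
    """
    clin = cohort.clinical if isinstance(cohort, SimulatedCohort) else cohort
    s = scores.scores if isinstance(scores, ScoreTable) else pd.Series(scores, dtype=float)
    common = s.index.intersection(clin.frame.index)
    use = clin.frame.loc[common, "prednisone_use"].astype(bool)
    x = s[common][~use].to_numpy(dtype=float)  # non-users
    y = s[common][use].to_numpy(dtype=float)  # users
    if len(x) == 0 or len(y) == 0:
        raise ConfigError(
            "recover_suppression needs both prednisone strata non-empty "
            f"(got {len(x)} non-users, {len(y)} users)"
        )
    est = float(x.mean() - y.mean())
    df = len(x) + len(y) - 2
    if df > 0 and (len(x) > 1 or len(y) > 1):
        sp2 = (
            (len(x) - 1) * np.var(x, ddof=1) if len(x) > 1 else 0.0
        ) + ((len(y) - 1) * np.var(y, ddof=1) if len(y) > 1 else 0.0)
        sp = math.sqrt(sp2 / df)
        se = sp * math.sqrt(1 / len(x) + 1 / len(y))
    else:
        se = math.inf
    return SuppressionEstimate(est, float(se), len(x), len(y))
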