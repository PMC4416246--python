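"""IFN-score computation.

The IFN-score of a sample is the arithmetic mean of the log2 expression
values of a fixed panel of type I interferon response genes (IRGs).  Three
panels are built in:

* ``IRG8`` — EPSTI1, HERC5, IFI44L, ISG15, LY6E, MX1, MX2, RSAD2;
* ``IRG7`` — IRG8 without HERC5 (for microarrays lacking a HERC5 probe);
* ``IRG3`` — EPSTI1, MX1, RSAD2 (the most predictive reduced panel).

Samples missing too large a fraction of the panel are excluded rather than
scored on a thin slice of the signature; the default tolerance (25% of the
panel) admits the 7-of-8 HERC5-missing case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ScoringError
from .expression import ExpressionMatrix

IFN_HIGH = "IFN-high"
IFN_LOW = "IFN-low"


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered panel of gene symbols (uppercase, no duplicates)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        up = tuple(g.strip().upper() for g in self.genes)
        object.__setattr__(self, "genes", up)
        if len(set(up)) != len(up):
            raise ScoringError(f"gene set {self.name!r} contains duplicate symbols")
        if not up:
            raise ScoringError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        """Load a user-defined panel: one gene symbol per line, '#' comments."""
        path = Path(path)
        genes = [
            ln.strip()
            for ln in path.read_text().splitlines()
            if ln.strip() and not ln.strip().startswith("#")
        ]
        return cls(name or path.stem, tuple(genes))


IRG8 = GeneSet(
    "IRG8", ("EPSTI1", "HERC5", "IFI44L", "ISG15", "LY6E", "MX1", "MX2", "RSAD2")
)
IRG7 = GeneSet("IRG7", tuple(g for g in IRG8.genes if g != "HERC5"))
IRG3 = GeneSet("IRG3", ("EPSTI1", "MX1", "RSAD2"))

GENE_SETS: dict[str, GeneSet] = {"irg8": IRG8, "irg7": IRG7, "irg3": IRG3}


@dataclass
class ScoreTable:
    """Per-sample IFN-scores plus bookkeeping of panel coverage.

    Attributes
    ----------
    table
        DataFrame indexed by sample id with columns ``ifn_score`` (log2
        units), ``genes_used`` (int) and ``genes_missing`` (list of symbols);
        ``genes_used + len(genes_missing)`` equals the panel size.
    gene_set_name
        Name of the panel the scores were computed from.
    excluded
        ``(sample_id, available_fraction)`` pairs for samples dropped because
        too much of the panel was unavailable.
    """

    table: pd.DataFrame
    gene_set_name: str = ""
    excluded: list[tuple[str, float]] = field(default_factory=list)

    @property
    def scores(self) -> pd.Series:
        return self.table["ifn_score"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_scores(
        cls,
        scores: Mapping[str, float] | pd.Series,
        gene_set: GeneSet | None = None,
        gene_set_name: str = "",
    ) -> "ScoreTable":
        """Build a ScoreTable from bare per-sample scores (e.g. external data)."""
        s = pd.Series(scores, dtype=float)
        n = len(gene_set) if gene_set is not None else 0
        tab = pd.DataFrame(
            {
                "ifn_score": s,
                "genes_used": n,
                "genes_missing": [[] for _ in range(len(s))],
            }
        )
        tab.index.name = "sample_id"
        name = gene_set.name if gene_set is not None else gene_set_name
        return cls(tab, name)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.table.copy()
        out["genes_missing"] = out["genes_missing"].map(";".join)
        out.index.name = "sample_id"
        out.to_csv(path)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path, index_col="sample_id", dtype={"sample_id": str})
        df.index = df.index.astype(str)
        if "ifn_score" not in df.columns:
            raise ScoringError(f"{path}: missing required column 'ifn_score'")
        if "genes_used" not in df.columns:
            df["genes_used"] = 0
        if "genes_missing" in df.columns:
            df["genes_missing"] = (
                df["genes_missing"].fillna("").map(lambda s: [g for g in s.split(";") if g])
            )
        else:
            df["genes_missing"] = [[] for _ in range(len(df))]
        return cls(df[["ifn_score", "genes_used", "genes_missing"]])


def compute_ifn_score(
    m: ExpressionMatrix,
    gene_set: GeneSet = IRG8,
    min_gene_fraction: float = 0.75,
) -> ScoreTable:
    """Mean log2 expression of the panel genes, per sample.

    Per sample the score averages the panel genes that are present in the
    matrix and non-missing for that sample.  Samples whose available-gene
    fraction falls below ``min_gene_fraction`` are excluded and reported in
    ``ScoreTable.excluded``.
    """
    if not 0 < min_gene_fraction <= 1:
        raise ScoringError("min_gene_fraction must be in (0, 1]")
    if m.n_samples == 0:
        raise ScoringError("expression matrix has no samples")
    present = [g for g in gene_set.genes if g in set(m.gene_ids)]
    if not present:
        raise ScoringError(
            f"none of the {len(gene_set)} genes of panel {gene_set.name!r} "
            "are present in the expression matrix"
        )
    absent = [g for g in gene_set.genes if g not in set(m.gene_ids)]
    sub = m.data.loc[present]
    available = sub.notna()
    n_avail = available.sum(axis=0)
    frac = n_avail / len(gene_set)
    keep = frac >= min_gene_fraction

    scores = sub.mean(axis=0, skipna=True)
    rows = []
    for s in m.sample_ids:
        if not keep[s]:
            continue
        miss = absent + [g for g in present if not available.at[g, s]]
        rows.append((s, float(scores[s]), int(n_avail[s]), miss))
    excluded = [(s, float(frac[s])) for s in m.sample_ids if not keep[s]]

    tab = pd.DataFrame(
        rows, columns=["sample_id", "ifn_score", "genes_used", "genes_missing"]
    ).set_index("sample_id")
    return ScoreTable(tab, gene_set.name, excluded)


def dichotomize_ifn_status(
    scores: ScoreTable | pd.Series,
    cutoff: float,
    inclusive: bool = False,
) -> pd.Series:
    """Label each sample IFN-high / IFN-low at a score cut-off.

    By default the comparison is strict (score > cutoff ⇒ IFN-high), matching
    the cut-off rule of the prediction stage; ``inclusive=True`` switches to
    score ≥ cutoff.
    """
    if not np.isfinite(cutoff):
        raise ScoringError("cutoff must be finite")
    s = scores.scores if isinstance(scores, ScoreTable) else pd.Series(scores, dtype=float)
    above = s >= cutoff if inclusive else s > cutoff
    return above.map({True: IFN_HIGH, False: IFN_LOW}).rename("ifn_status")
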