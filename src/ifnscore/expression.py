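"""Expression-matrix I/O and cross-platform harmonisation.

Blood IRG expression arrives from two measurement platforms — DNA microarray
(log2 or linear intensities) and multiplex qPCR (ΔCt values, already
reference-gene normalised).  This module reads either into a common
gene-by-sample log2 matrix, median-centres each gene within its platform, and
merges platforms on the shared gene set so one score can be computed across
the combined cohort.

Conventions
-----------
* All values are stored on the log2 scale.  ΔCt maps to −ΔCt (one ΔCt unit is
  one doubling, and a *larger* ΔCt means *less* transcript).
* Gene symbols are uppercased on input; duplicates (after uppercasing) are an
  error, never silently collapsed.
* Missing cells are permitted (empty field in the delimited text) and are
  ignored by medians.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ExpressionError

logger = logging.getLogger(__name__)

MICROARRAY = "microarray"
QPCR = "qpcr"
PLATFORMS = (MICROARRAY, QPCR)
SCALES = ("log2", "linear", "delta_ct")

_CENTER_TOL = 1e-9


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log2 expression values with platform provenance.

    Parameters
    ----------
    data
        DataFrame indexed by uppercase gene symbol, one column per sample.
    platforms
        Mapping sample id -> platform name (one of ``PLATFORMS``).  Single-
        platform matrices simply map every sample to the same platform.
    centered
        True once each gene row has had its per-platform median subtracted.
    """

    data: pd.DataFrame
    platforms: dict[str, str] = field(default_factory=dict)
    centered: bool = False

    def __post_init__(self) -> None:
        genes = list(self.data.index)
        samples = list(self.data.columns)
        dup_g = _duplicates(genes)
        if dup_g:
            raise ExpressionError(f"duplicate gene symbol(s): {', '.join(dup_g)}")
        dup_s = _duplicates(samples)
        if dup_s:
            raise ExpressionError(f"duplicate sample id(s): {', '.join(dup_s)}")
        missing_prov = [s for s in samples if s not in self.platforms]
        if missing_prov:
            raise ExpressionError(
                f"no platform recorded for sample(s): {', '.join(missing_prov[:10])}"
            )
        bad = set(self.platforms.values()) - set(PLATFORMS)
        if bad:
            raise ExpressionError(f"unknown platform(s): {sorted(bad)}")

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def platform_of(self, sample_id: str) -> str:
        return self.platforms[sample_id]

    def validate_centered(self, tol: float = _CENTER_TOL) -> None:
        """Check the centering invariant: per gene, within each platform's
        sample block, the median of non-missing values is 0 (within *tol*)."""
        if not self.centered:
            return
        for plat in sorted(set(self.platforms.values())):
            cols = [s for s in self.sample_ids if self.platforms[s] == plat]
            block = self.data[cols]
            med = block.median(axis=1, skipna=True).dropna()
            off = med[med.abs() > tol]
            if len(off):
                raise ExpressionError(
                    f"centered matrix has non-zero median for gene(s) "
                    f"{list(off.index[:5])} on platform {plat}"
                )


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


def read_expression_table(
    path: str | Path,
    platform: str,
    scale: str,
    sep: str | None = None,
    offset: float | None = None,
) -> ExpressionMatrix:
    """Read a delimited gene-by-sample table into a log2 ExpressionMatrix.

    The file layout is one header row (``gene`` + sample ids), first column
    gene symbol, remaining cells numbers or empty (missing).

    ``scale`` controls the transform to log2:

    ``log2``
        values pass through unchanged;
    ``linear``
        values are log2-transformed; non-positive values are a hard error
        unless an explicit ``offset`` is supplied, which is added to *all*
        values first (silent flooring would distort downstream scores);
    ``delta_ct``
        ΔCt value x is stored as −x (relative log2 expression).
    """
    path = Path(path)
    if platform not in PLATFORMS:
        raise ExpressionError(f"unknown platform {platform!r}; expected one of {PLATFORMS}")
    if scale not in SCALES:
        raise ExpressionError(f"unknown scale {scale!r}; expected one of {SCALES}")

    delim = _infer_sep(path, sep)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise ExpressionError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    if len(header) < 2:
        raise ExpressionError(f"{path}: header must contain a gene column and ≥1 sample")
    sample_ids = header[1:]
    dup_s = _duplicates(sample_ids)
    if dup_s:
        raise ExpressionError(f"duplicate sample id(s): {', '.join(dup_s)}")

    genes: list[str] = []
    values: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):  # 1-based line numbers incl. header
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise ExpressionError(
                f"{path}: line {i} has {len(row)} fields, expected {len(header)}"
            )
        gene = row[0].strip().upper()
        if not gene:
            raise ExpressionError(f"{path}: line {i} has an empty gene symbol")
        parsed: list[float] = []
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "":
                parsed.append(math.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ExpressionError(
                    f"{path}: unparseable value {cell!r} at line {i}, "
                    f"column {sample_ids[j]!r}"
                ) from None
        genes.append(gene)
        values.append(parsed)

    dup_g = _duplicates(genes)
    if dup_g:
        raise ExpressionError(
            f"duplicate gene symbol(s) after uppercasing: {', '.join(dup_g)}"
        )

    arr = np.asarray(values, dtype=float).reshape(len(genes), len(sample_ids))
    if scale == "linear":
        if offset is not None:
            arr = arr + offset
        nonpos = np.argwhere(arr <= 0)
        # NaN comparisons are False, so missing cells pass through
        if len(nonpos):
            gi, sj = nonpos[0]
            raise ExpressionError(
                f"non-positive linear value {arr[gi, sj]!r} for gene {genes[gi]}, "
                f"sample {sample_ids[sj]!r}; supply an explicit offset to shift values"
            )
        arr = np.log2(arr)
    elif scale == "delta_ct":
        arr = -arr

    data = pd.DataFrame(arr, index=genes, columns=sample_ids)
    return ExpressionMatrix(data, {s: platform for s in sample_ids}, centered=False)


def write_expression_table(
    m: ExpressionMatrix,
    path: str | Path,
    sep: str | None = None,
    provenance: bool = True,
) -> Path:
    """Write the matrix as delimited text (always on the log2 scale).

    Missing values are written as empty cells.  A JSON sidecar
    ``<path>.provenance.json`` records the sample → platform map unless
    ``provenance`` is False.
    """
    path = Path(path)
    delim = _infer_sep(path, sep)
    out = m.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=delim, na_rep="", float_format="%.17g")
    if provenance:
        side = path.with_name(path.name + ".provenance.json")
        side.write_text(
            json.dumps({"centered": m.centered, "platforms": m.platforms}, indent=2)
        )
    return path


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene row's median (ignoring missing values).

    Centering is per gene within one platform's samples and is the step that
    makes microarray and qPCR values poolable.  Gene rows that are entirely
    missing carry no information and are dropped with a warning.  A second
    centering pass is refused: it would silently hide a bookkeeping bug.
    """
    if m.centered:
        raise ExpressionError("matrix is already centered; refusing to center twice")
    med = m.data.median(axis=1, skipna=True)
    all_missing = med.isna()
    data = m.data
    if all_missing.any():
        dropped = list(data.index[all_missing])
        logger.warning(
            "dropping %d gene row(s) with no non-missing values: %s",
            len(dropped),
            ", ".join(dropped),
        )
        data = data.loc[~all_missing]
        med = med[~all_missing]
    return ExpressionMatrix(data.sub(med, axis=0), dict(m.platforms), centered=True)


def merge_platforms(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge centered per-platform matrices on their common gene set.

    Output genes are the intersection of the input gene sets (ordered as in
    the first input); samples are concatenated preserving input order, with
    per-sample platform provenance carried through.
    """
    if not matrices:
        raise ExpressionError("merge_platforms needs at least one matrix")
    uncentered = [i for i, m in enumerate(matrices) if not m.centered]
    if uncentered:
        raise ExpressionError(
            f"input matrix(es) at position(s) {uncentered} are not centered; "
            "median-center each platform before merging"
        )
    seen: dict[str, int] = {}
    collisions: list[str] = []
    for i, m in enumerate(matrices):
        for s in m.sample_ids:
            if s in seen:
                collisions.append(s)
            seen[s] = i
    if collisions:
        raise ExpressionError(
            f"overlapping sample id(s) across platforms: {', '.join(sorted(set(collisions))[:10])}"
        )
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ExpressionError("empty gene intersection across input matrices")
    genes = [g for g in matrices[0].gene_ids if g in common]
    data = pd.concat([m.data.loc[genes] for m in matrices], axis=1)
    platforms: dict[str, str] = {}
    for m in matrices:
        platforms.update(m.platforms)
    return ExpressionMatrix(data, platforms, centered=True)
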