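"""Exhaustive reference x target correlation-with-age grid.

For every candidate reference region the uptake matrix is converted to
SUVr (row-wise division by the subject's reference value) and every target
region's SUVr column is correlated with age (plain Pearson; sex enters
only the voxelwise model, not the grid). The grid's per-reference summary
— the median and the strongest (most negative) coefficient over defined
targets — is the score the selection rule operates on.

Undefined entries (the self-normalized reference, whose SUVr is the
constant 1, and any otherwise constant column) are marked NaN and excluded
from summaries rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import RegionUptakeMatrix

#: Relative peak-to-peak tolerance under which a column counts as constant.
_CONSTANT_RTOL = 1e-9


def normalize_by_reference(matrix: RegionUptakeMatrix, reference: str) -> RegionUptakeMatrix:
    """SUVr matrix: every entry divided by the subject's reference value.

    The reference column becomes identically 1. Raises if any subject has a
    non-positive reference value, naming the first offender.
    """
    ref = matrix.column(reference)
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive reference value for subject {matrix.subject_ids[bad[0]]!r} "
            f"in reference {reference!r}"
        )
    return RegionUptakeMatrix(
        values=matrix.values / ref[:, None],
        subject_ids=list(matrix.subject_ids),
        region_names=list(matrix.region_names),
        ages=matrix.ages.copy(),
        sexes=matrix.sexes.copy(),
    )


def _is_constant(x: np.ndarray) -> bool:
    return float(np.ptp(x)) <= _CONSTANT_RTOL * max(float(np.max(np.abs(x))), 1e-300)


def pearson_with_age(x: np.ndarray, ages: np.ndarray) -> float:
    """Product-moment correlation of a value vector with age.

    Returns NaN (the undefined marker) when ``x`` or ``ages`` is constant.
    """
    x = np.asarray(x, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if x.shape != ages.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {ages.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if _is_constant(x) or _is_constant(ages):
        return float("nan")
    xc = x - x.mean()
    ac = ages - ages.mean()
    r = float(xc @ ac / np.sqrt((xc @ xc) * (ac @ ac)))
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class CorrelationGrid:
    """Reference x target Pearson-with-age coefficients; NaN = undefined."""

    r: np.ndarray  # (n_references, n_targets)
    reference_names: list[str]
    target_names: list[str]
    n_subjects: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.reference_names), len(self.target_names)):
            raise ValueError("grid shape does not match names")
        defined = self.r[np.isfinite(self.r)]
        if defined.size and (defined.min() < -1 or defined.max() > 1):
            raise ValueError("correlation entries outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.reference_names, columns=self.target_names)


@dataclass
class NormalizationSummary:
    """Per-reference median and strongest (most negative) coefficient."""

    region_names: list[str]
    median_r: np.ndarray
    strongest_r: np.ndarray
    system_label: str = ""

    def __post_init__(self) -> None:
        self.median_r = np.asarray(self.median_r, dtype=float)
        self.strongest_r = np.asarray(self.strongest_r, dtype=float)
        if not (len(self.region_names) == self.median_r.size == self.strongest_r.size):
            raise ValueError("summary fields must align")
        if np.any(self.strongest_r > self.median_r + 1e-15):
            raise ValueError("strongest_r must be <= median_r for every reference")

    def median_of(self, region: str) -> float:
        return float(self.median_r[self.region_names.index(region)])

    def strongest_of(self, region: str) -> float:
        return float(self.strongest_r[self.region_names.index(region)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_names,
                "strongest_r": self.strongest_r,
                "median_r": self.median_r,
            }
        )


def compute_correlation_grid(matrix: RegionUptakeMatrix) -> CorrelationGrid:
    """The full reference x target grid over all regions in the matrix.

    Each row normalizes by one reference and correlates every target SUVr
    column with age; the diagonal (reference = target) is undefined by
    construction and marked NaN.
    """
    if matrix.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    names = matrix.region_names
    ages = matrix.ages.astype(float)
    n_regions = len(names)
    r = np.full((n_regions, n_regions), np.nan)

    ages_c = ages - ages.mean()
    age_ss = float(ages_c @ ages_c)
    if age_ss == 0:
        raise ValueError("ages are constant; correlations undefined")

    for i, ref in enumerate(names):
        suvr = normalize_by_reference(matrix, ref).values
        col_mean = suvr.mean(axis=0)
        xc = suvr - col_mean
        ss = np.einsum("ij,ij->j", xc, xc)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = (ages_c @ xc) / np.sqrt(ss * age_ss)
        ptp = suvr.max(axis=0) - suvr.min(axis=0)
        constant = ptp <= _CONSTANT_RTOL * np.maximum(np.abs(suvr).max(axis=0), 1e-300)
        row[constant] = np.nan
        row[i] = np.nan  # self-normalized reference: SUVr constant 1
        r[i] = np.clip(row, -1.0, 1.0)
    return CorrelationGrid(r=r, reference_names=list(names), target_names=list(names), n_subjects=matrix.n_subjects)


def summarize_reference(grid: CorrelationGrid, system_label: str = "") -> NormalizationSummary:
    """Median and minimum (most negative) coefficient per reference row.

    Medians use the average-of-two convention for even counts; undefined
    entries are excluded. A reference row with no defined entry is an error.
    """
    n_defined = np.isfinite(grid.r).sum(axis=1)
    if np.any(n_defined == 0):
        bad = [n for n, c in zip(grid.reference_names, n_defined) if c == 0]
        raise ValueError(f"references with no defined grid entries: {bad}")
    with np.errstate(all="ignore"):
        median = np.nanmedian(grid.r, axis=1)
        strongest = np.nanmin(grid.r, axis=1)
    return NormalizationSummary(
        region_names=list(grid.reference_names),
        median_r=median,
        strongest_r=strongest,
        system_label=system_label,
    )


def save_grid(grid: CorrelationGrid, path) -> None:
    grid.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def load_grid(path) -> CorrelationGrid:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CorrelationGrid(
        r=df.to_numpy(dtype=float),
        reference_names=[str(i) for i in df.index],
        target_names=[str(c) for c in df.columns],
        n_subjects=0,
    )
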