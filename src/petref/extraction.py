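"""Region-of-interest extraction: subject volumes -> uptake matrix.

Regional values are unweighted arithmetic means of voxel intensities over
each label's voxels, plus a pooled whole-grey-matter entry computed over
the union of all non-brainstem regions (the proportional-scaling
denominator). The subjects x regions matrix is the object every
normalization downstream operates on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import WHOLE_GREY_MATTER, ParcellationAtlas


@dataclass
class RegionUptakeMatrix:
    """Subjects x regions mean uptake with subject covariates attached."""

    values: np.ndarray  # (n_subjects, n_regions), strictly positive on valid input
    subject_ids: list[str]
    region_names: list[str]
    ages: np.ndarray
    sexes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.sexes = np.asarray(self.sexes, dtype=int)
        n, r = self.values.shape
        if not (n == len(self.subject_ids) == self.ages.size == self.sexes.size):
            raise ValueError("subject dimension mismatch")
        if r != len(self.region_names):
            raise ValueError("region dimension mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("uptake matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def column(self, region_name: str) -> np.ndarray:
        try:
            j = self.region_names.index(region_name)
        except ValueError:
            raise KeyError(f"unknown region name: {region_name!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.region_names)
        df.insert(0, "sex", self.sexes)
        df.insert(0, "age", self.ages)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def extract_region_means(
    volume: np.ndarray,
    atlas: ParcellationAtlas,
    include_whole_grey_matter: bool = True,
) -> np.ndarray:
    """Per-region mean voxel value, optionally appending the grey-matter union.

    The appended pooled entry is the plain mean over the union mask of all
    non-brainstem regions, i.e. the voxel-count-weighted combination of the
    constituent regional means.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != atlas.label_grid.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match atlas grid {atlas.label_grid.shape}"
        )
    counts = ndimage.sum_labels(np.ones_like(volume), labels=atlas.label_grid, index=atlas.region_ids)
    if np.any(counts == 0):
        empty = [n for n, c in zip(atlas.region_names, counts) if c == 0]
        raise ValueError(f"empty regions in atlas: {empty}")
    means = ndimage.mean(volume, labels=atlas.label_grid, index=atlas.region_ids)
    means = np.asarray(means, dtype=float)
    if not include_whole_grey_matter:
        return means
    gm = atlas.grey_matter_mask()
    if not gm.any():
        raise ValueError("grey-matter union mask is empty")
    return np.append(means, volume[gm].mean())


def build_uptake_matrix(
    manifest_path,
    atlas: ParcellationAtlas,
    include_whole_grey_matter: bool = True,
) -> RegionUptakeMatrix:
    """Extract the uptake matrix for every subject listed in a manifest TSV.

    Rows keep manifest order; volume paths are resolved relative to the
    manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "age", "sex", "path"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    region_names = list(atlas.region_names)
    if include_whole_grey_matter:
        region_names = region_names + [WHOLE_GREY_MATTER]
    rows = []
    for rec in manifest.itertuples(index=False):
        vol_path = manifest_path.parent / str(rec.path)
        try:
            vol = np.asarray(nib.load(str(vol_path)).dataobj, dtype=float)
        except Exception as exc:
            raise IOError(f"cannot read volume for subject {rec.subject_id!r}: {exc}") from exc
        rows.append(extract_region_means(vol, atlas, include_whole_grey_matter))
    return RegionUptakeMatrix(
        values=np.vstack(rows) if rows else np.empty((0, len(region_names))),
        subject_ids=[str(s) for s in manifest["subject_id"]],
        region_names=region_names,
        ages=manifest["age"].to_numpy(dtype=float),
        sexes=manifest["sex"].to_numpy(dtype=int),
    )


def matrix_from_region_means(
    cohort,
    means: np.ndarray,
    region_names: list[str],
) -> RegionUptakeMatrix:
    """Wrap simulated per-subject regional means as a RegionUptakeMatrix."""
    return RegionUptakeMatrix(
        values=np.asarray(means, dtype=float),
        subject_ids=[m.subject_id for m in cohort],
        region_names=list(region_names),
        ages=np.array([m.age for m in cohort]),
        sexes=np.array([m.sex for m in cohort]),
    )


def save_uptake_matrix(matrix: RegionUptakeMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_uptake_matrix(path) -> RegionUptakeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["subject_id", "age", "sex"]
    region_names = [c for c in df.columns if c not in meta_cols]
    return RegionUptakeMatrix(
        values=df[region_names].to_numpy(dtype=float),
        subject_ids=[str(s) for s in df["subject_id"]],
        region_names=region_names,
        ages=df["age"].to_numpy(dtype=float),
        sexes=df["sex"].to_numpy(dtype=int),
    )


def scale_volumes_by_reference(
    volumes: np.ndarray,
    atlas: ParcellationAtlas,
    reference: str,
) -> np.ndarray:
    """Divide each subject's volume voxel-wise by that subject's reference ROI mean.

    Image-level counterpart of matrix-level SUVr normalization; ``reference``
    may be any atlas region or the pooled whole-grey-matter entry.
    """
    volumes = np.asarray(volumes, dtype=float)
    out = np.empty_like(volumes)
    if reference == WHOLE_GREY_MATTER:
        mask = atlas.grey_matter_mask()
    else:
        mask = atlas.region_mask(reference)
        if not mask.any():
            raise ValueError(f"empty reference region {reference!r}")
    for i, vol in enumerate(volumes):
        ref = vol[mask].mean()
        if ref <= 0:
            raise ValueError(f"non-positive reference mean for subject index {i}")
        out[i] = vol / ref
    return out
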