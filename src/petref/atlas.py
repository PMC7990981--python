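"""Labelled brain parcellations and anatomical structure grouping.

A :class:`ParcellationAtlas` is an integer label volume (0 = outside brain)
together with region names, voxel geometry and a region -> structure map.
Fine atlas regions (e.g. the individual cerebellum lobules and vermis
subdivisions of AAL-style parcellations) are grouped into the anatomical
structure a practitioner would normalize by: all ``Cerebelum_*`` and
``Vermis_*`` regions belong to the "cerebellum" structure, ``Pons`` to
"pons", and every other region is its own structure.

A procedural toy atlas (ellipsoidal brain mask partitioned by
nearest-centroid growth from seeded voxels) supports fully synthetic
pipelines; real labelmaps are read from NIfTI plus a TSV lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Brainstem region names excluded from the grey-matter union.
BRAINSTEM_REGIONS = frozenset({"Midbrain", "Pons", "Medulla"})

#: Name of the pooled grey-matter pseudo-region used for proportional scaling.
WHOLE_GREY_MATTER = "Whole grey-matter"


def infer_structure(region_name: str) -> str:
    """Map a region name to its anatomical structure.

    Cerebellum lobules and vermis subdivisions are pooled into
    ``"cerebellum"``, the pons maps to ``"pons"``; any other region is its
    own structure (identity grouping).
    """
    if region_name.startswith(("Cerebelum_", "Vermis_")):
        return "cerebellum"
    if region_name == "Pons":
        return "pons"
    return region_name


@dataclass
class ParcellationAtlas:
    """Integer-labelled parcellation in a fixed voxel grid.

    Attributes
    ----------
    label_grid
        3D integer array; 0 marks background, positive values are region
        labels.
    region_ids
        Ordered positive integer labels, one per region.
    region_names
        One name per id, same order.
    voxel_size_mm
        Voxel edge lengths in mm, one per axis.
    structure_of
        Total map from region name to structure name.
    """

    label_grid: np.ndarray
    region_ids: list[int]
    region_names: list[str]
    voxel_size_mm: tuple[float, float, float]
    structure_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim != 3:
            raise ValueError("label_grid must be 3D")
        self.region_ids = [int(i) for i in self.region_ids]
        if len(self.region_ids) != len(self.region_names):
            raise ValueError("region_ids and region_names length mismatch")
        if any(i <= 0 for i in self.region_ids):
            raise ValueError("region ids must be positive")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("duplicate region names")
        grid_labels = set(np.unique(self.label_grid).tolist()) - {0}
        declared = set(self.region_ids)
        if grid_labels != declared:
            orphans = sorted(grid_labels - declared)
            missing = sorted(declared - grid_labels)
            raise ValueError(
                f"label/lookup mismatch: orphan labels in grid {orphans}, "
                f"declared ids absent from grid {missing}"
            )
        if not self.structure_of:
            self.structure_of = {n: infer_structure(n) for n in self.region_names}
        if set(self.structure_of) != set(self.region_names):
            raise ValueError("structure_of must be total over region_names")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def brain_mask(self) -> np.ndarray:
        """Boolean mask of all labelled voxels."""
        return self.label_grid > 0

    def region_mask(self, region_name: str) -> np.ndarray:
        return self.label_grid == self._id_of(region_name)

    def grey_matter_mask(self) -> np.ndarray:
        """Union of all regions outside the brainstem.

        Stands in for a whole-grey-matter mask when treating proportional
        scaling (global-mean normalization) as a 'reference region'.
        """
        brainstem_ids = [
            i for i, n in zip(self.region_ids, self.region_names)
            if n in BRAINSTEM_REGIONS
        ]
        mask = self.label_grid > 0
        for i in brainstem_ids:
            mask &= self.label_grid != i
        return mask

    def _id_of(self, region_name: str) -> int:
        try:
            return self.region_ids[self.region_names.index(region_name)]
        except ValueError:
            raise KeyError(f"unknown region name: {region_name!r}") from None

    def map_to_structure(self, region_name: str) -> str:
        """Structure of a named region; raises for unknown names."""
        if region_name not in self.structure_of:
            raise KeyError(f"unknown region name: {region_name!r}")
        return self.structure_of[region_name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParcellationAtlas):
            return NotImplemented
        return (
            np.array_equal(self.label_grid, other.label_grid)
            and self.region_ids == other.region_ids
            and self.region_names == other.region_names
            and self.voxel_size_mm == other.voxel_size_mm
            and self.structure_of == other.structure_of
        )


def build_toy_atlas(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    n_regions: int,
    seed: int,
) -> ParcellationAtlas:
    """Generate an ellipsoidal brain mask partitioned into contiguous regions.

    The mask is an axis-aligned ellipsoid filling ~80% of the grid extent.
    ``n_regions`` seed voxels are drawn uniformly from the mask and every
    in-mask voxel is assigned to its nearest seed (distances in mm), which
    yields contiguous Voronoi-style regions. Deterministic given ``seed``.

    Regions are named ``R001``, ``R002``, ...; when ``n_regions >= 10`` the
    last three are renamed ``Cerebelum_toy_L``, ``Vermis_toy`` and ``Pons``
    so that structure grouping is exercised on toy data.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if any(s < 8 for s in grid_shape):
        raise ValueError("grid_shape axes must each be >= 8")

    center = (np.asarray(grid_shape) - 1) / 2.0
    semi = np.asarray(grid_shape) * 0.4
    idx = np.indices(grid_shape)
    dist2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    mask = dist2 <= 1.0

    in_mask = np.flatnonzero(mask.ravel())
    if n_regions > in_mask.size:
        raise ValueError("atlas oversegmented: more regions than mask voxels")

    rng = np.random.default_rng(seed)
    seed_flat = rng.choice(in_mask, size=n_regions, replace=False)
    seed_ijk = np.column_stack(np.unravel_index(seed_flat, grid_shape))

    voxel_size = np.asarray(voxel_size_mm, dtype=float)
    coords = np.column_stack(np.unravel_index(in_mask, grid_shape)) * voxel_size
    seed_mm = seed_ijk * voxel_size
    # nearest-centroid assignment; argmin breaks ties by lowest seed index
    d2 = ((coords[:, None, :] - seed_mm[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)

    labels = np.zeros(grid_shape, dtype=np.int32)
    labels.ravel()[in_mask] = assign + 1

    names = [f"R{k:03d}" for k in range(1, n_regions + 1)]
    if n_regions >= 10:
        names[-3:] = ["Cerebelum_toy_L", "Vermis_toy", "Pons"]

    return ParcellationAtlas(
        label_grid=labels,
        region_ids=list(range(1, n_regions + 1)),
        region_names=names,
        voxel_size_mm=tuple(voxel_size),
    )


# -- NIfTI / TSV round-trip --------------------------------------------------

def save_atlas(atlas: ParcellationAtlas, labelmap_path, lookup_path) -> None:
    """Write the label grid as NIfTI-1 and the lookup as TSV.

    The lookup has header ``id<TAB>name<TAB>structure``.
    """
    affine = np.diag(list(atlas.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(atlas.label_grid.astype(np.int32), affine)
    nib.save(img, str(labelmap_path))
    pd.DataFrame(
        {
            "id": atlas.region_ids,
            "name": atlas.region_names,
            "structure": [atlas.structure_of[n] for n in atlas.region_names],
        }
    ).to_csv(lookup_path, sep="\t", index=False)


def load_atlas(labelmap_path, lookup_path) -> ParcellationAtlas:
    """Load a labelmap NIfTI plus a region lookup TSV.

    The lookup must have columns ``id`` and ``name``; an optional
    ``structure`` column carries the grouping (default: each region is its
    own structure). Labels present in the grid but absent from the lookup
    are reported as orphans.
    """
    labelmap_path = Path(labelmap_path)
    if not labelmap_path.exists():
        raise FileNotFoundError(f"labelmap not found: {labelmap_path}")
    img = nib.load(str(labelmap_path))
    grid = np.asarray(img.dataobj).astype(np.int32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])

    lookup = pd.read_csv(lookup_path, sep="\t")
    if not {"id", "name"} <= set(lookup.columns):
        raise ValueError("lookup TSV must have columns 'id' and 'name'")
    ids = [int(i) for i in lookup["id"]]
    names = [str(n) for n in lookup["name"]]

    grid_labels = set(np.unique(grid).tolist()) - {0}
    orphans = sorted(grid_labels - set(ids))
    if orphans:
        raise ValueError(f"labels present in grid but absent from lookup: {orphans}")

    if "structure" in lookup.columns:
        structure_of = dict(zip(names, (str(s) for s in lookup["structure"])))
    else:
        structure_of = {n: n for n in names}

    return ParcellationAtlas(
        label_grid=grid,
        region_ids=ids,
        region_names=names,
        voxel_size_mm=voxel_size,
        structure_of=structure_of,
    )
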