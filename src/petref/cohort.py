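"""Seeded synthetic FDG-PET ageing cohorts.

The generator reproduces the statistical structure the normalization
analysis relies on, nothing more:

* regional mean uptake declines linearly with age,
  ``m_ik = b_k * (1 + s_k * (age_i - a0)) * g_i + eps_ik``,
  with per-region baseline ``b_k`` (arbitrary uptake units) and fractional
  slope ``s_k`` (per year);
* a per-subject multiplicative global factor ``g_i ~ lognormal(0, sd)``
  standing in for injected dose and scanner sensitivity — the nuisance that
  makes proportional scaling necessary in the first place;
* additive regional and voxel noise;
* scanner-resolution Gaussian post-smoothing (8 mm FWHM for a conventional
  camera, 4 mm for a digital one).

Two cohort presets mirror typical conventional/digital healthy-control
databases: n=56, age 50+/-17 (range 21-78), 33 women, 8 mm smoothing; and
n=78, age 58+/-16 (range 22-87), 42 women, 4 mm smoothing.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import ParcellationAtlas

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_UPTAKE_FLOOR = 1e-6


@dataclass(frozen=True)
class CohortConfig:
    """Cohort demographics, noise levels and scanner preset."""

    n_subjects: int
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float
    n_women: int
    smoothing_fwhm_mm: float
    noise_sd: float = 0.05  # additive noise, fraction of regional baseline
    global_factor_sd: float = 0.2  # log-scale sd of per-subject multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.n_women > self.n_subjects:
            raise ValueError("n_women cannot exceed n_subjects")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        if self.noise_sd < 0 or self.global_factor_sd < 0:
            raise ValueError("noise levels must be >= 0")


#: Conventional-camera healthy-control preset (8 mm post-smoothing).
CONVENTIONAL = CohortConfig(
    n_subjects=56, age_mean=50.0, age_sd=17.0, age_min=21.0, age_max=78.0,
    n_women=33, smoothing_fwhm_mm=8.0,
)

#: Digital-camera healthy-control preset (4 mm post-smoothing).
DIGITAL = CohortConfig(
    n_subjects=78, age_mean=58.0, age_sd=16.0, age_min=22.0, age_max=87.0,
    n_women=42, smoothing_fwhm_mm=4.0,
)

PRESETS = {"conventional": CONVENTIONAL, "digital": DIGITAL}


def preset(name: str, **overrides) -> CohortConfig:
    """A named preset, optionally with fields overridden (e.g. ``seed=3``)."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return dataclasses.replace(base, **overrides)


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    age: float
    sex: int  # 0 = man, 1 = woman


@dataclass
class AgeingModel:
    """Linear-in-age fractional decline of regional uptake.

    ``slope`` is the fractional change per year relative to ``baseline``
    (so -0.005 means 0.5% loss per year); ``reference_age`` is the age at
    which uptake equals baseline exactly.
    """

    region_names: list[str]
    baseline: np.ndarray
    slope: np.ndarray
    reference_age: float

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        if not (len(self.region_names) == self.baseline.size == self.slope.size):
            raise ValueError("region_names, baseline, slope must align")
        if np.any(self.baseline <= 0):
            raise ValueError("baselines must be positive")

    def mean_uptake(self, age: float) -> np.ndarray:
        """Noise-free regional means at a given age."""
        return self.baseline * (1.0 + self.slope * (age - self.reference_age))

    def validate_over(self, age_min: float, age_max: float) -> None:
        """Reject slopes that drive the deterministic mean non-positive."""
        for edge in (age_min, age_max):
            if np.any(self.mean_uptake(edge) <= 0):
                raise ValueError("degenerate ageing model: non-positive mean uptake in age range")


def default_ageing_model(
    region_names: list[str],
    seed: int = 0,
    slope_range: tuple[float, float] = (-0.007, -0.002),
    flat_regions: tuple[str, ...] = ("Pons",),
    reference_age: float = 58.0,
) -> AgeingModel:
    """Plausible ageing model: every region declines except the planted ones.

    Baselines are uniform in [80, 120] uptake units; slopes uniform in
    ``slope_range`` (default 0.2-0.7% loss per year, the order of magnitude
    of reported grey-matter metabolic decline); regions listed in
    ``flat_regions`` get slope 0 and act as age-invariant references.
    """
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(80.0, 120.0, size=len(region_names))
    slope = rng.uniform(slope_range[0], slope_range[1], size=len(region_names))
    for name in flat_regions:
        if name in region_names:
            slope[region_names.index(name)] = 0.0
    return AgeingModel(list(region_names), baseline, slope, reference_age)


# -- sampling ----------------------------------------------------------------

def sample_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> list[SubjectMeta]:
    """Draw subject metadata: truncated-normal ages, exact sex counts.

    Ages come from normal(age_mean, age_sd) rejection-sampled into
    [age_min, age_max]; exactly ``n_women`` subjects are coded 1, positions
    shuffled. Deterministic given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    ages = np.empty(config.n_subjects)
    filled = 0
    while filled < config.n_subjects:
        draw = rng.normal(config.age_mean, config.age_sd, size=config.n_subjects)
        keep = draw[(draw >= config.age_min) & (draw <= config.age_max)]
        take = min(keep.size, config.n_subjects - filled)
        ages[filled:filled + take] = keep[:take]
        filled += take
    sexes = np.zeros(config.n_subjects, dtype=int)
    sexes[: config.n_women] = 1
    sexes = rng.permutation(sexes)
    return [
        SubjectMeta(subject_id=f"sub-{i + 1:03d}", age=float(ages[i]), sex=int(sexes[i]))
        for i in range(config.n_subjects)
    ]


def _subject_rng(config: CohortConfig, subject_id: str) -> np.random.Generator:
    # stable per-subject stream: seed path (cohort seed, crc32 of the id)
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(subject_id.encode())])
    )


def simulate_region_means(
    meta: SubjectMeta,
    model: AgeingModel,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One subject's regional mean uptakes under the ageing model.

    ``m_ik = b_k (1 + s_k (age_i - a0)) g_i + eps_ik`` with
    ``g_i ~ lognormal(0, global_factor_sd)`` and
    ``eps_ik ~ normal(0, noise_sd * b_k)``; values floored at a small
    positive epsilon. With ``rng=None`` the stream is derived from the
    cohort seed and the subject id, so repeated calls agree.
    """
    model.validate_over(config.age_min, config.age_max)
    if rng is None:
        rng = _subject_rng(config, meta.subject_id)
    det = model.mean_uptake(meta.age)
    g = float(rng.lognormal(0.0, config.global_factor_sd)) if config.global_factor_sd > 0 else 1.0
    eps = rng.normal(0.0, config.noise_sd * model.baseline) if config.noise_sd > 0 else 0.0
    return np.maximum(det * g + eps, _UPTAKE_FLOOR)


def gaussian_smooth_volume(
    volume: np.ndarray, fwhm_mm: float, voxel_size_mm: tuple[float, float, float]
) -> np.ndarray:
    """Separable Gaussian smoothing with a kernel stated in mm FWHM.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2)) / voxel_size``; FWHM 0 is
    the identity. Boundary mode is zero-padding (no signal outside the
    field of view).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigma = [fwhm_mm * FWHM_TO_SIGMA / float(v) for v in voxel_size_mm]
    return ndimage.gaussian_filter(volume, sigma=sigma, mode="constant", cval=0.0)


def render_subject_volume(
    region_means: np.ndarray,
    atlas: ParcellationAtlas,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Paint regional means into the atlas grid, add voxel noise, smooth.

    Voxel noise is normal with sd ``0.5 * noise_sd * regional mean``
    (half the regional noise scale). After smoothing at the preset FWHM the
    background is re-masked to 0.
    """
    region_means = np.asarray(region_means, dtype=float)
    if region_means.size != atlas.n_regions:
        raise ValueError("need one mean per atlas region")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    lut = np.zeros(max(atlas.region_ids) + 1)
    lut[np.asarray(atlas.region_ids)] = region_means
    vol = lut[atlas.label_grid]
    mask = atlas.brain_mask()
    if config.noise_sd > 0:
        sd = np.zeros_like(lut)
        sd[np.asarray(atlas.region_ids)] = 0.5 * config.noise_sd * region_means
        vol = vol + rng.normal(0.0, 1.0, size=vol.shape) * sd[atlas.label_grid]
    vol[~mask] = 0.0
    vol = gaussian_smooth_volume(vol, config.smoothing_fwhm_mm, atlas.voxel_size_mm)
    vol[~mask] = 0.0
    return vol


def simulate_cohort(
    atlas: ParcellationAtlas,
    model: AgeingModel,
    config: CohortConfig,
) -> tuple[list[SubjectMeta], np.ndarray, np.ndarray]:
    """Sample a cohort and render every subject volume.

    Returns ``(cohort, region_means, volumes)`` with ``region_means`` of
    shape (n_subjects, n_regions) and ``volumes`` of shape
    (n_subjects, *grid). Fully deterministic given ``config.seed``.
    """
    cohort = sample_cohort(config)
    means = np.empty((len(cohort), atlas.n_regions))
    volumes = np.empty((len(cohort),) + atlas.label_grid.shape)
    for i, meta in enumerate(cohort):
        srng = _subject_rng(config, meta.subject_id)
        means[i] = simulate_region_means(meta, model, config, rng=srng)
        volumes[i] = render_subject_volume(means[i], atlas, config, rng=srng)
    return cohort, means, volumes


# -- on-disk cohorts ---------------------------------------------------------

def write_cohort(
    cohort: list[SubjectMeta],
    volumes: np.ndarray,
    atlas: ParcellationAtlas,
    out_dir,
) -> Path:
    """Write one float32 NIfTI per subject plus a TSV manifest.

    The manifest has columns subject_id, age, sex, path (relative to the
    manifest's directory). Returns the manifest path.
    """
    if len(cohort) != len(volumes):
        raise ValueError("need exactly one volume per subject")
    ids = [m.subject_id for m in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError(f"path collision: duplicate subject ids {sorted(set(i for i in ids if ids.count(i) > 1))}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(atlas.voxel_size_mm) + [1.0])
    rows = []
    for meta, vol in zip(cohort, volumes):
        fname = f"{meta.subject_id}.nii"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(out_dir / fname))
        rows.append({"subject_id": meta.subject_id, "age": meta.age, "sex": meta.sex, "path": fname})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
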