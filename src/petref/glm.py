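"""Mass-univariate age regression with permutation FWE and cluster volumetrics.

The same linear model y = b0 + b1*age + b2*sex + e is fit independently at
every in-mask voxel; decline with age is tested one-sided through the
contrast c = (0, -1, 0), so t > 0 means loss of uptake per year.

Family-wise error is controlled by a maxT permutation null: the age column
is permuted across subjects (sex stays attached to its subject), the
maximum in-mask t is recorded per permutation, and the critical value is
the empirical (1 - alpha) quantile of that null. Supra-threshold voxels
are grouped into 26-connected clusters and reported as counts, mm^3
volumes and peak t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import SubjectMeta

#: Contrast testing metabolic decline with age (positive t = decline).
NEGATIVE_AGE_CONTRAST = (0.0, -1.0, 0.0)

# residual sums of squares below this fraction of the data sum of squares
# count as an exact fit (sigma^2 = 0)
_RSS_RTOL = 1e-12


@dataclass
class DesignMatrix:
    """Intercept + age + sex design with a default negative-age contrast."""

    X: np.ndarray
    contrast: np.ndarray = field(default_factory=lambda: np.asarray(NEGATIVE_AGE_CONTRAST))
    column_names: tuple[str, ...] = ("intercept", "age", "sex")

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 3:
            raise ValueError("design matrix must be n x 3 (intercept, age, sex)")
        if self.contrast.shape != (3,):
            raise ValueError("contrast must have length 3")
        if self.X.shape[0] < 5:
            raise ValueError("need at least 5 subjects")
        if np.linalg.matrix_rank(self.X) < 3:
            raise ValueError(
                "rank-deficient design (constant age or single-sex cohort cannot "
                "separate intercept, age and sex effects)"
            )

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def df(self) -> int:
        return self.X.shape[0] - 3


def build_design_matrix(
    cohort: list[SubjectMeta],
    contrast: tuple[float, float, float] = NEGATIVE_AGE_CONTRAST,
) -> DesignMatrix:
    """Design matrix (1, age, sex) from subject metadata."""
    ages = np.array([m.age for m in cohort], dtype=float)
    sexes = np.array([m.sex for m in cohort], dtype=float)
    X = np.column_stack([np.ones_like(ages), ages, sexes])
    return DesignMatrix(X=X, contrast=np.asarray(contrast, dtype=float))


@dataclass
class VoxelOLSFit:
    """Per-voxel OLS estimates over a flat in-mask voxel axis."""

    beta: np.ndarray  # (3, n_voxels)
    sigma2: np.ndarray  # (n_voxels,)
    mask: np.ndarray  # boolean 3D
    df: int


@dataclass
class Cluster:
    id: int
    n_voxels: int
    volume_mm3: float
    t_max: float
    peak_ijk: tuple[int, int, int]


@dataclass
class GLMResult:
    """T-map, threshold and cluster table of one normalization's age regression."""

    tmap: np.ndarray
    df: int
    threshold_t: float
    alpha: float
    clusters: list[Cluster]
    total_significant_mm3: float
    t_max: float

    def cluster_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": c.id,
                    "n_voxels": c.n_voxels,
                    "volume_mm3": c.volume_mm3,
                    "t_max": c.t_max,
                    "peak_i": c.peak_ijk[0],
                    "peak_j": c.peak_ijk[1],
                    "peak_k": c.peak_ijk[2],
                }
                for c in self.clusters
            ],
            columns=["id", "n_voxels", "volume_mm3", "t_max", "peak_i", "peak_j", "peak_k"],
        )


def _stack_in_mask(volumes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise ValueError("volumes must be stacked as (n_subjects, nx, ny, nz)")
    if volumes.shape[1:] != mask.shape:
        raise ValueError("volume grid does not match mask")
    Y = volumes[:, mask]
    if not np.all(np.isfinite(Y)):
        subj, vox = np.argwhere(~np.isfinite(Y))[0]
        ijk = tuple(np.argwhere(mask)[vox])
        raise ValueError(f"non-finite value for subject index {int(subj)} at voxel {ijk}")
    return Y


def fit_voxelwise_ols(
    volumes: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
) -> VoxelOLSFit:
    """OLS at every in-mask voxel: beta = (X'X)^-1 X'y, sigma2 = RSS/(n-3)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    Y = _stack_in_mask(volumes, mask)
    X = design.X
    if X.shape[0] != Y.shape[0]:
        raise ValueError("number of volumes does not match design rows")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    yc = Y - Y.mean(axis=0)
    scale = np.einsum("ij,ij->j", yc, yc) + 1.0
    rss[rss <= _RSS_RTOL * scale] = 0.0  # exact fits: numerical dust -> true zero
    return VoxelOLSFit(beta=beta, sigma2=rss / design.df, mask=mask, df=design.df)


def contrast_tmap(fit: VoxelOLSFit, design: DesignMatrix, contrast=None) -> np.ndarray:
    """3D t-map of the contrast; 0 outside the mask.

    Degenerate voxels: sigma2 = 0 with a nonzero contrast estimate maps to
    +/-inf (the sign of the estimate); 0/0 maps to 0 and never clusters.
    """
    c = np.asarray(design.contrast if contrast is None else contrast, dtype=float)
    if c.shape != (3,):
        raise ValueError("contrast must have length 3")
    XtX_inv = np.linalg.inv(design.X.T @ design.X)
    c_var = float(c @ XtX_inv @ c)
    num = c @ fit.beta
    # a contrast estimate at numerical-noise level counts as exactly zero
    beta_scale = np.linalg.norm(fit.beta, axis=0)
    num = np.where(np.abs(num) <= 1e-10 * beta_scale, 0.0, num)
    den = np.sqrt(fit.sigma2 * c_var)
    t = np.zeros_like(num)
    ok = den > 0
    t[ok] = num[ok] / den[ok]
    exact = ~ok & (num != 0)
    t[exact] = np.sign(num[exact]) * np.inf
    tmap = np.zeros(fit.mask.shape)
    tmap[fit.mask] = t
    return tmap


def _max_t_null(
    Y: np.ndarray,
    design: DesignMatrix,
    n_perm: int,
    rng: np.random.Generator,
    batch: int = 100,
) -> np.ndarray:
    """maxT permutation null: age column permuted, sex kept attached."""
    n, V = Y.shape
    c = design.contrast
    yty = np.einsum("ij,ij->j", Y, Y)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        Xp = np.broadcast_to(design.X, (b, n, 3)).copy()
        for k in range(b):
            Xp[k, :, 1] = design.X[rng.permutation(n), 1]
        XtX = np.einsum("pni,pnj->pij", Xp, Xp)
        XtX_inv = np.linalg.inv(XtX)
        XtY = np.einsum("pni,nv->piv", Xp, Y)
        beta = np.einsum("pij,pjv->piv", XtX_inv, XtY)
        rss = np.maximum(yty[None, :] - np.einsum("piv,piv->pv", XtY, beta), 0.0)
        sigma2 = rss / design.df
        c_var = np.einsum("i,pij,j->p", c, XtX_inv, c)
        num = np.einsum("i,piv->pv", c, beta)
        den = np.sqrt(sigma2 * c_var[:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(den > 0, num / den, 0.0)
        out[done:done + b] = t.max(axis=1)
        done += b
    return out


def permutation_fwe_threshold(
    volumes: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Critical t controlling family-wise error at level alpha.

    Empirical (1 - alpha) quantile (upper interpolation) of the maxT null
    obtained by permuting ages across subjects. Deterministic given seed.
    """
    if n_perm < 100:
        raise ValueError("insufficient permutations: need n_perm >= 100")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    mask = np.asarray(mask, dtype=bool)
    Y = _stack_in_mask(volumes, mask)
    rng = np.random.default_rng(seed)
    null = _max_t_null(Y, design, n_perm, rng)
    if alpha == 1.0:
        return float(null.min())
    return float(np.quantile(null, 1.0 - alpha, method="higher"))


def label_clusters(
    tmap: np.ndarray,
    threshold_t: float,
    voxel_size_mm: tuple[float, float, float],
    connectivity: int = 26,
) -> list[Cluster]:
    """Connected components of {t >= threshold}, largest volume first.

    ``connectivity`` is 6, 18 or 26 (the SPM-style default); the peak is
    the maximum-t voxel, ties broken by lowest linear index.
    """
    if not np.isfinite(threshold_t):
        raise ValueError("threshold must be finite")
    structures = {6: 1, 18: 2, 26: 3}
    if connectivity not in structures:
        raise ValueError("connectivity must be 6, 18 or 26")
    struct = ndimage.generate_binary_structure(3, structures[connectivity])
    supra = tmap >= threshold_t
    labeled, n = ndimage.label(supra, structure=struct)
    voxel_volume = float(np.prod(voxel_size_mm))
    clusters = []
    for lab in range(1, n + 1):
        flat = np.flatnonzero(labeled.ravel() == lab)
        vals = tmap.ravel()[flat]
        t_max = float(vals.max())
        peak_flat = int(flat[int(np.argmax(vals))])  # argmax -> lowest linear index on ties
        clusters.append(
            Cluster(
                id=lab,
                n_voxels=int(flat.size),
                volume_mm3=float(flat.size * voxel_volume),
                t_max=t_max,
                peak_ijk=tuple(int(v) for v in np.unravel_index(peak_flat, tmap.shape)),
            )
        )
    clusters.sort(key=lambda cl: (-cl.volume_mm3, cl.id))
    for rank, cl in enumerate(clusters, start=1):
        cl.id = rank
    return clusters


def run_glm(
    volumes: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
    fixed_t: float | None = None,
) -> GLMResult:
    """Full stage: fit, t-map, FWE threshold (or a fixed t), clusters.

    ``fixed_t`` reuses a critical value computed elsewhere — the mechanism
    for analysing a second cohort at the same t level as the first.
    """
    fit = fit_voxelwise_ols(volumes, design, mask)
    tmap = contrast_tmap(fit, design)
    if fixed_t is None:
        threshold = permutation_fwe_threshold(
            volumes, design, mask, n_perm=n_perm, alpha=alpha, seed=seed
        )
    else:
        threshold = float(fixed_t)
    clusters = label_clusters(tmap, threshold, voxel_size_mm, connectivity)
    finite = tmap[np.asarray(mask, dtype=bool)]
    return GLMResult(
        tmap=tmap,
        df=design.df,
        threshold_t=threshold,
        alpha=alpha,
        clusters=clusters,
        total_significant_mm3=float(sum(c.volume_mm3 for c in clusters)),
        t_max=float(finite.max()) if finite.size else float("nan"),
    )


def fold_ratios(total_mm3: dict[str, float]) -> dict[str, float]:
    """Fold-ratio of the largest total significant volume over each other.

    ``{"pons": 143330, "cerebellum": 84216}`` -> the best reference ("pons")
    gets ratio 1.0 relative entries for the others (best/other).
    """
    if len(total_mm3) < 2:
        raise ValueError("need at least 2 normalizations to compare")
    best_ref = max(total_mm3, key=lambda k: total_mm3[k])
    best = total_mm3[best_ref]
    return {
        ref: (float("inf") if vol == 0 else best / vol)
        for ref, vol in total_mm3.items()
    }


def significant_volume_report(results: dict[str, GLMResult]) -> pd.DataFrame:
    """Comparison table across normalizations.

    Per reference: total significant mm^3, global t max, and the fold-ratio
    of the best (largest-volume) reference against this one.
    """
    totals = {ref: res.total_significant_mm3 for ref, res in results.items()}
    folds = fold_ratios(totals)
    rows = [
        {
            "reference": ref,
            "total_significant_mm3": res.total_significant_mm3,
            "t_max": res.t_max,
            "threshold_t": res.threshold_t,
            "n_clusters": len(res.clusters),
            "fold_of_best_vs_this": folds[ref],
        }
        for ref, res in results.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        "total_significant_mm3", ascending=False, ignore_index=True
    )
    return df
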