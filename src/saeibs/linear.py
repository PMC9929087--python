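"""Matrix-decomposition ancestry methods: PCA, unnormalized PCA (UPCA) and
SUGIBS, under a common fit/project contract.

PCA mean-centers each SNP and scales by sqrt(p(1-p)) with p the observed
alternate-allele frequency (missing calls mean-imputed first).  UPCA is a
truncated SVD of the raw additive codes with no centering or scaling, which
trades clustering sharpness for outlier robustness.  SUGIBS decomposes
D^{-1/2} X where D is the IBS similarity-degree diagonal; targets project as
D̃^{-1} Y V with D̃ from the target-reference cross IBS, which corrects for
per-sample artifact load (missingness, genotyping error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import ibs as ibs_mod
from .matrix import MISSING, GenotypeMatrix

LINEAR_METHODS = ("pca", "upca", "sugibs")


@dataclass
class AncestryScores:
    """n x k latent coordinates; axis order follows the singular values."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class AncestryModel:
    """A fitted linear ancestry embedding with its projection state."""

    method: str
    k: int
    loadings: np.ndarray  # m x k, orthonormal columns
    singular_values: np.ndarray  # length k, descending positive
    center: Optional[np.ndarray] = None  # per-SNP centering (pca)
    scale: Optional[np.ndarray] = None  # per-SNP scaling (pca)
    impute: Optional[np.ndarray] = None  # per-SNP fill value for missing codes
    training_scores: Optional[AncestryScores] = None

    def __post_init__(self) -> None:
        sv = np.asarray(self.singular_values, dtype=float)
        if (np.diff(sv) > 1e-9 * max(sv[0], 1.0)).any():
            raise ValueError("singular values must be non-increasing")
        self.singular_values = sv


def _fix_signs(v: np.ndarray, *others: np.ndarray) -> tuple[np.ndarray, ...]:
    """Force the largest-magnitude loading of each axis positive, flipping
    the paired score columns accordingly (cross-run comparability)."""
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return (v * signs, *[o * signs for o in others])


def _truncated_svd(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not 1 <= k <= min(mat.shape):
        raise ValueError(f"k={k} out of range for matrix of shape {mat.shape}")
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    return u[:, :k], s[:k], vt[:k].T


def _pca_design(x: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean-imputed, centered, frequency-scaled allele-count design matrix."""
    a = x.allele_counts()  # {0,1,2} with NaN for missing
    col_mean = np.nanmean(a, axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    miss = np.isnan(a)
    a[miss] = np.broadcast_to(col_mean, a.shape)[miss]
    p = col_mean / 2.0
    scale = np.sqrt(p * (1.0 - p))
    scale[scale == 0.0] = 1.0  # monomorphic SNP: no variance to rescale
    design = (a - col_mean) / scale
    return design, col_mean, scale, col_mean


def fit_pca(x: GenotypeMatrix, k: int) -> AncestryModel:
    """Classical genotype PCA via truncated SVD of the normalized matrix."""
    design, center, scale, impute = _pca_design(x)
    u, s, v = _truncated_svd(design, k)
    v, u = _fix_signs(v, u)
    scores = AncestryScores(values=u * s, sample_ids=list(x.sample_ids))
    return AncestryModel(
        method="pca", k=k, loadings=v, singular_values=s,
        center=center, scale=scale, impute=impute, training_scores=scores,
    )


def fit_upca(x: GenotypeMatrix, k: int, center: bool = False,
             drop_trivial_axis: bool = True) -> AncestryModel:
    """Unnormalized PCA: truncated SVD of the raw additive codes.

    Missing codes (-2) are kept as-is; that raw treatment is precisely what
    the degree correction in SUGIBS/SAE-IBS compensates for.  Without
    centering the leading singular axis is a near-constant grand-mean
    direction, not an ancestry axis; by default it is discarded and the k
    non-trivial axes are reported (the spectral-decomposition convention).
    """
    raw = x.values.astype(float)
    c = raw.mean(axis=0) if center else None
    design = raw - c if center else raw
    skip = 1 if (drop_trivial_axis and not center) else 0
    u, s, v = _truncated_svd(design, k + skip)
    u, s, v = u[:, skip:], s[skip:], v[:, skip:]
    v, u = _fix_signs(v, u)
    scores = AncestryScores(values=u * s, sample_ids=list(x.sample_ids))
    return AncestryModel(
        method="upca", k=k, loadings=v, singular_values=s,
        center=c, training_scores=scores,
    )


def fit_sugibs(x: GenotypeMatrix, k: int, drop_trivial_axis: bool = True) -> AncestryModel:
    """SUGIBS: truncated SVD of D^{-1/2} X with D the IBS degree diagonal.

    As with any degree-generalized spectral embedding, the leading axis is
    trivial (the degree-weighted mean direction) and is discarded by default.
    """
    s_mat = ibs_mod.ibs_matrix(x)
    d = ibs_mod.degree(s_mat)
    design = x.values.astype(float) * d.diagonal_power(-0.5)[:, None]
    skip = 1 if drop_trivial_axis else 0
    u, s, v = _truncated_svd(design, k + skip)
    u, s, v = u[:, skip:], s[skip:], v[:, skip:]
    v, u = _fix_signs(v, u)
    scores = AncestryScores(values=u * s, sample_ids=list(x.sample_ids))
    return AncestryModel(
        method="sugibs", k=k, loadings=v, singular_values=s, training_scores=scores,
    )


def project_linear(
    model: AncestryModel,
    y: GenotypeMatrix,
    x_ref: Optional[GenotypeMatrix] = None,
) -> AncestryScores:
    """Project target genotypes onto a fitted linear ancestry space.

    PCA applies the stored imputation/centering/scaling then right-multiplies
    by the loadings; UPCA multiplies the raw codes; SUGIBS rescales rows by
    the inverse cross-IBS degrees D̃^{-1} (requires the training reference).
    """
    if y.n_variants != model.loadings.shape[0]:
        raise ValueError(
            f"variant mismatch: target has {y.n_variants} SNPs, model expects "
            f"{model.loadings.shape[0]}"
        )
    if model.method == "pca":
        a = y.allele_counts()
        miss = np.isnan(a)
        a[miss] = np.broadcast_to(model.impute, a.shape)[miss]
        design = (a - model.center) / model.scale
    elif model.method == "upca":
        design = y.values.astype(float)
        if model.center is not None:
            design = design - model.center
    elif model.method == "sugibs":
        if x_ref is None:
            raise ValueError("SUGIBS projection requires the training reference")
        d_t = ibs_mod.degree(ibs_mod.cross_ibs(y, x_ref))
        design = y.values.astype(float) * d_t.diagonal_power(-1.0)[:, None]
    else:
        raise ValueError(f"not a linear method: {model.method!r}")
    return AncestryScores(values=design @ model.loadings, sample_ids=list(y.sample_ids))


def save_model(model: AncestryModel, path) -> None:
    """Serialize a linear model to a single .npz container."""
    arrays = {
        "loadings": model.loadings,
        "singular_values": model.singular_values,
        "method": np.array(model.method),
        "k": np.array(model.k),
        "format_version": np.array(1),
    }
    for name in ("center", "scale", "impute"):
        val = getattr(model, name)
        if val is not None:
            arrays[name] = val
    np.savez(path, **arrays)


def load_model(path) -> AncestryModel:
    with np.load(path, allow_pickle=False) as data:
        return AncestryModel(
            method=str(data["method"]),
            k=int(data["k"]),
            loadings=data["loadings"],
            singular_values=data["singular_values"],
            center=data["center"] if "center" in data else None,
            scale=data["scale"] if "scale" in data else None,
            impute=data["impute"] if "impute" in data else None,
        )
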