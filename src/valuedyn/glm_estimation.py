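"""Voxelwise GLM estimation, contrasts, and group permutation inference.

Run-level models are ordinary least squares per voxel (optionally with
per-voxel AR(1) Cochrane-Orcutt prewhitening); run contrasts combine
within subject by inverse-variance fixed effects; group inference is a
one-sample sign-flip permutation test on subject effect maps with optional
threshold-free cluster enhancement (TFCE), controlling the family-wise
error rate over the analysis mask.  A conjunction operation intersects two
significance masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError
from .fmri_design import DesignMatrix


# --------------------------------------------------------------------------
# run-level GLM
# --------------------------------------------------------------------------

@dataclass
class GLMResult:
    """Per-voxel betas and residual variance for one run.

    ``betas`` is (n_regressors, n_voxels); ``xtx_inv`` is either a single
    (p, p) matrix (OLS) or a (n_voxels, p, p) stack (AR(1) whitening, where
    each voxel has its own whitened design).
    """

    betas: np.ndarray
    resid_var: np.ndarray
    dof: int
    column_names: list[str]
    xtx_inv: np.ndarray
    whitening: str = "none"
    rho: np.ndarray | None = None
    rank_deficient: bool = False
    flagged_empty: set = field(default_factory=set)


def fit_run_glm(Y: np.ndarray, design: DesignMatrix,
                whitening: str = "none") -> GLMResult:
    """Fit a run's time series (n_scans x n_voxels) against the design.

    ``whitening='ar1'`` estimates each voxel's lag-1 residual
    autocorrelation from the OLS fit, applies the Cochrane-Orcutt
    transform to data and design, and refits (one scan and one degree of
    freedom are lost).  A rank-deficient design is fitted with the
    pseudoinverse and flagged; contrasts touching flagged empty columns
    are refused downstream.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise InvalidArgumentError(
            f"data has {Y.shape[0]} scans but design has {X.shape[0]} rows")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    rank_deficient = rank < p
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    dof = n - rank
    if whitening == "none":
        resid_var = (resid ** 2).sum(axis=0) / max(dof, 1)
        xtx_inv = pinv @ pinv.T
        return GLMResult(betas=betas, resid_var=resid_var, dof=dof,
                         column_names=list(design.column_names), xtx_inv=xtx_inv,
                         whitening="none", rank_deficient=rank_deficient,
                         flagged_empty=set(design.flagged_empty))
    if whitening != "ar1":
        raise InvalidArgumentError(f"unknown whitening {whitening!r}")

    # per-voxel AR(1): rho from OLS residuals, Cochrane-Orcutt refit
    num = (resid[1:] * resid[:-1]).sum(axis=0)
    den = (resid ** 2).sum(axis=0)
    rho = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    rho = np.clip(rho, -0.99, 0.99)
    nv = Y.shape[1]
    Yw = Y[1:] - rho[None, :] * Y[:-1]                       # (n-1, v)
    Xw = X[None, 1:, :] - rho[:, None, None] * X[None, :-1, :]  # (v, n-1, p)
    XtX = np.einsum("vnp,vnq->vpq", Xw, Xw)
    XtY = np.einsum("vnp,nv->vp", Xw, Yw)
    xtx_inv = np.linalg.pinv(XtX)
    betas_w = np.einsum("vpq,vq->pv", xtx_inv, XtY)
    resid_w = Yw - np.einsum("vnp,pv->nv", Xw, betas_w)
    dof_w = (n - 1) - rank
    resid_var = (resid_w ** 2).sum(axis=0) / max(dof_w, 1)
    return GLMResult(betas=betas_w, resid_var=resid_var, dof=dof_w,
                     column_names=list(design.column_names), xtx_inv=xtx_inv,
                     whitening="ar1", rho=rho, rank_deficient=rank_deficient,
                     flagged_empty=set(design.flagged_empty))


@dataclass
class ContrastMap:
    """Effect size, standard error and t per voxel for one contrast."""

    effect: np.ndarray
    se: np.ndarray
    t: np.ndarray
    weights: np.ndarray
    dof: int


def contrast_vector(column_names: list[str], weights: dict[str, float]) -> np.ndarray:
    w = np.zeros(len(column_names))
    for name, val in weights.items():
        if name not in column_names:
            raise InvalidArgumentError(f"no column named {name!r}")
        w[column_names.index(name)] = val
    return w


def contrast(result: GLMResult, weights) -> ContrastMap:
    """w' beta with SE from the (whitened) normal-equation covariance."""
    if isinstance(weights, dict):
        for name in weights:
            if name in result.flagged_empty and weights[name] != 0:
                raise InvalidArgumentError(
                    f"contrast touches flagged empty column {name!r}")
        w = contrast_vector(result.column_names, weights)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != result.betas.shape[0]:
            raise InvalidArgumentError("weight vector length != n_regressors")
        for name in result.flagged_empty:
            if w[result.column_names.index(name)] != 0:
                raise InvalidArgumentError(
                    f"contrast touches flagged empty column {name!r}")
    effect = w @ result.betas
    if result.xtx_inv.ndim == 2:
        quad = float(w @ result.xtx_inv @ w)
        var = result.resid_var * quad
    else:
        quad = np.einsum("p,vpq,q->v", w, result.xtx_inv, w)
        var = result.resid_var * quad
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    return ContrastMap(effect=effect, se=se, t=t, weights=w, dof=result.dof)


def combine_runs(maps: list[ContrastMap]) -> ContrastMap:
    """Inverse-variance fixed-effects combination of run contrast maps."""
    if not maps:
        raise InvalidArgumentError("no maps to combine")
    if len(maps) == 1:
        return maps[0]
    shapes = {m.effect.shape for m in maps}
    if len(shapes) != 1:
        raise InvalidArgumentError("contrast maps are on different voxel grids")
    w = np.array([1.0 / np.maximum(m.se, 1e-300) ** 2 for m in maps])
    eff = np.array([m.effect for m in maps])
    wsum = w.sum(axis=0)
    effect = (w * eff).sum(axis=0) / wsum
    se = 1.0 / np.sqrt(wsum)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    dof = int(sum(m.dof for m in maps))
    return ContrastMap(effect=effect, se=se, t=t, weights=maps[0].weights, dof=dof)


# --------------------------------------------------------------------------
# TFCE
# --------------------------------------------------------------------------

def tfce(stat_map: np.ndarray, E: float = 0.5, H: float = 2.0,
         dh: float | None = None, connectivity: int = 6,
         mask: np.ndarray | None = None, n_steps: int = 100) -> np.ndarray:
    """Threshold-free cluster enhancement of a (3-D) statistic map.

    For each voxel v the enhanced value is the sum over thresholds
    h in {dh, 2 dh, ..., max} of ``e(h, v)**E * h**H * dh`` where e(h, v)
    is the extent of the connected component (face connectivity by
    default) containing v among voxels with value >= h.  Only positive
    values are enhanced; negative effects should be tested by negating the
    map.  ``dh`` defaults to max / n_steps.
    """
    if connectivity not in (6, 18, 26):
        raise InvalidArgumentError("connectivity must be 6, 18 or 26")
    stat = np.asarray(stat_map, dtype=float)
    if mask is not None:
        stat = np.where(np.asarray(mask, dtype=bool), stat, 0.0)
    peak = stat.max() if stat.size else 0.0
    out = np.zeros_like(stat)
    if peak <= 0:
        return out
    if dh is None:
        dh = peak / n_steps
    if dh <= 0:
        raise InvalidArgumentError("dh must be positive")
    structure = ndimage.generate_binary_structure(stat.ndim,
                                                  {6: 1, 18: 2, 26: 3}[connectivity])
    h = dh
    while h <= peak + 1e-12 * peak:
        sup = stat >= h - 1e-12 * peak
        labels, n_lab = ndimage.label(sup, structure=structure)
        if n_lab == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out += np.where(sup, sizes[labels] ** float(E) * h ** float(H) * dh, 0.0)
        h += dh
    return out


# --------------------------------------------------------------------------
# group permutation inference
# --------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Sign-flip permutation test over an analysis mask.

    ``p_corr`` holds FWE-corrected p-values (1.0 outside the mask);
    the smallest attainable p is ``1 / (n_perm + 1)``.
    """

    t_obs: np.ndarray
    enhanced_obs: np.ndarray
    p_corr: np.ndarray
    max_null: np.ndarray
    n_perm: int
    mask: np.ndarray
    alternative: str
    enhancement: str
    seed: int
    tfce_params: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return (self.p_corr < alpha) & self.mask


def group_permutation_test(subject_maps, mask: np.ndarray | None = None,
                           n_perm: int = 5000, enhancement: str = "tfce",
                           alternative: str = "greater", seed: int = 0,
                           E: float = 0.5, H: float = 2.0,
                           dh: float | None = None,
                           connectivity: int = 6) -> PermutationResult:
    """One-sample group inference by sign-flip permutation with TFCE.

    ``subject_maps`` is a list/array of per-subject 3-D effect maps.  The
    observed statistic is the one-sample t per voxel; the null
    distribution of the maximum (enhanced) statistic over the mask is
    built by randomly multiplying each subject's map by +/-1, giving
    FWE-corrected p-values ``(1 + #{null max >= observed}) / (n_perm + 1)``.
    ``alternative='two-sided'`` runs both directions and Bonferroni-doubles
    the smaller p (two one-sided tests at alpha/2).
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim < 2:
        raise InvalidArgumentError("need a stack of subject maps")
    n_subj = maps.shape[0]
    if n_subj < 6:
        raise InvalidArgumentError("need at least 6 subjects for sign-flip inference")
    if n_perm < 100:
        import warnings
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse",
                      stacklevel=2)
    vol_shape = maps.shape[1:]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol_shape:
        raise InvalidArgumentError("mask shape does not match maps")
    if not mask.any():
        raise InvalidArgumentError("analysis mask is empty")

    if alternative == "two-sided":
        lo = group_permutation_test(subject_maps, mask, n_perm, enhancement,
                                    "less", seed, E, H, dh, connectivity)
        hi = group_permutation_test(subject_maps, mask, n_perm, enhancement,
                                    "greater", seed, E, H, dh, connectivity)
        p = np.minimum(1.0, 2.0 * np.minimum(lo.p_corr, hi.p_corr))
        return PermutationResult(t_obs=hi.t_obs, enhanced_obs=hi.enhanced_obs,
                                 p_corr=p, max_null=hi.max_null, n_perm=n_perm,
                                 mask=mask, alternative="two-sided",
                                 enhancement=enhancement, seed=seed,
                                 tfce_params=hi.tfce_params)
    sign0 = -1.0 if alternative == "less" else 1.0
    if alternative not in ("greater", "less"):
        raise InvalidArgumentError(f"unknown alternative {alternative!r}")

    # bounding box of the mask keeps TFCE labelling cheap
    bbox = tuple(slice(idx.min(), idx.max() + 1) for idx in np.nonzero(mask))
    sub_mask = mask[bbox]
    flat = sign0 * maps[(slice(None),) + bbox].reshape(n_subj, -1)
    mvox = sub_mask.ravel()
    flat = flat[:, mvox]

    sumsq = (flat ** 2).sum(axis=0)  # invariant under sign flips

    def tstat(signed_sum):
        mean = signed_sum / n_subj
        var = (sumsq - n_subj * mean ** 2) / (n_subj - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, mean / np.sqrt(var / n_subj), 0.0)
        # zero-variance voxels: identical values across subjects; the t
        # statistic degenerates, so assign a large finite value of the
        # effect's sign
        degenerate = (var == 0) & (mean != 0)
        return np.where(degenerate, np.sign(mean) * 1e10, t)

    def enhance(tvals):
        if enhancement == "none":
            return tvals
        grid = np.zeros(sub_mask.shape)
        # cap keeps the threshold sweep finite when a degenerate
        # zero-variance voxel produced an effectively infinite t
        grid[sub_mask] = np.minimum(tvals, 1e4)
        enh = tfce(grid, E=E, H=H, dh=dh, connectivity=connectivity)
        return enh[sub_mask]

    if enhancement not in ("none", "tfce"):
        raise InvalidArgumentError(f"unknown enhancement {enhancement!r}")

    t_masked = tstat(flat.sum(axis=0))
    if enhancement == "tfce" and dh is None and t_masked.max() > 0:
        # one threshold grid, anchored at the observed peak, shared by the
        # observed map and every permutation
        dh = float(min(t_masked.max(), 1e4)) / 100.0
    enh_masked = enhance(t_masked)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        tv = tstat(signs[i] @ flat)
        max_null[i] = enhance(tv).max()
    exceed = (max_null[None, :] >= enh_masked[:, None] - 1e-12).sum(axis=1)
    p_masked = (1.0 + exceed) / (n_perm + 1.0)

    def unpack(vals, fill=0.0):
        grid = np.full(sub_mask.shape, fill)
        grid[sub_mask] = vals
        full = np.full(vol_shape, fill)
        full[bbox] = grid
        return full

    return PermutationResult(
        t_obs=unpack(sign0 * t_masked), enhanced_obs=unpack(enh_masked),
        p_corr=unpack(p_masked, fill=1.0), max_null=max_null, n_perm=n_perm,
        mask=mask, alternative=alternative, enhancement=enhancement, seed=seed,
        tfce_params={"E": E, "H": H, "dh": dh, "connectivity": connectivity})


def conjunction(sig_mask_a: np.ndarray, sig_mask_b: np.ndarray) -> np.ndarray:
    """Voxelwise logical AND of two significance masks on the same grid."""
    a = np.asarray(sig_mask_a, dtype=bool)
    b = np.asarray(sig_mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidArgumentError("significance masks are on different grids")
    return a & b
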