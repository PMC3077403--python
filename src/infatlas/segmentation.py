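"""Longitudinal tissue segmentation (framework step 1).

The anatomically mature 2-year timepoint is segmented with an adaptive
fuzzy c-means (AFCM) that alternates membership/centroid updates with a
smooth multiplicative gain estimate, so it tolerates residual intensity
inhomogeneity. The harder early timepoints are segmented by an EM
Gaussian-mixture scheme guided by spatial tissue priors; each tissue
class may carry several Gaussian components, which is what lets a single
"white matter" class cover both myelinated and unmyelinated WM in the
neonatal image. Finally, :func:`joint_longitudinal_segment` iterates
deformable registration of the mature segmentation onto the early image
with prior-guided re-segmentation, yielding both the early-age
segmentation and the cross-age deformation field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError, SpaceError
from .registration import (
    AffineTransform,
    affine_register,
    affine_to_field,
    apply_affine,
    compose,
    deformable_register,
    warp,
)
from .volumes_io import (
    DeformationField,
    LabelVolume,
    TISSUE_CLASSES,
    TissueMaps,
    Volume,
)

__all__ = [
    "GaussianMixtureSpec",
    "SegmentationResult",
    "afcm_segment",
    "prior_guided_segment",
    "joint_longitudinal_segment",
    "qc_volume_fractions",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class GaussianMixtureSpec:
    """Per-tissue Gaussian mixture: for each class (CSF, GM, WM) a list of
    (weight, mean, variance) components; weights sum to 1 within a class.
    The default neonatal configuration gives WM two components
    (unmyelinated/myelinated) and one each to CSF and GM."""

    components: dict[str, list[tuple[float, float, float]]]

    def __post_init__(self):
        for k in TISSUE_CLASSES:
            if k not in self.components:
                raise ParameterError(f"mixture spec missing class {k}")
            comps = self.components[k]
            wsum = sum(w for w, _, _ in comps)
            if abs(wsum - 1.0) > 1e-6:
                self.components[k] = [(w / wsum, m, v) for w, m, v in comps]
            if any(v <= 0 for _, _, v in comps):
                raise ParameterError(f"non-positive variance in class {k}")

    @classmethod
    def counts(cls, csf: int = 1, gm: int = 1, wm: int = 1) -> dict[str, int]:
        return {"CSF": csf, "GM": gm, "WM": wm}

    @property
    def n_components(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.components.items()}


@dataclass
class SegmentationResult:
    """Soft memberships + hard argmax labels + the fitted intensity model."""

    soft: TissueMaps
    hard: LabelVolume
    model: GaussianMixtureSpec | None
    converged: bool
    iterations: int
    objective_history: list[float] = field(default_factory=list)

    @classmethod
    def from_soft(cls, soft: TissueMaps, model=None, converged=True,
                  iterations=0, history=None) -> "SegmentationResult":
        return cls(soft, soft.hard(), model, converged, iterations,
                   list(history or []))


def _mean_class_dice(a: np.ndarray, b: np.ndarray) -> float:
    vals = []
    for lab in (1, 2, 3):
        na, nb = (a == lab).sum(), (b == lab).sum()
        if na + nb == 0:
            vals.append(1.0)
        else:
            vals.append(2.0 * ((a == lab) & (b == lab)).sum() / (na + nb))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# AFCM


def afcm_segment(vol: Volume, mask: np.ndarray, n_classes: int = 3,
                 fuzziness: float = 2.0, gain_smoothness_mm: float = 50.0,
                 tol: float = 1e-5, max_iter: int = 50,
                 class_order: tuple[str, ...] = TISSUE_CLASSES,
                 estimate_gain: bool = True) -> SegmentationResult:
    """Adaptive fuzzy c-means with a smooth multiplicative gain field.

    Minimises sum_k sum_x u_k(x)^m (y(x) - g(x) c_k)^2 subject to
    sum_k u_k = 1. Membership and centroid updates are the exact
    coordinate minimisers; the gain update (wide-Gaussian-smoothed
    log-residual, geometric mean 1) is accepted only when it lowers the
    objective, so the recorded objective history is non-increasing.

    ``class_order`` names the tissue classes in ascending-centroid order;
    the default (CSF, GM, WM) suits T1-like contrast, while T2-like
    neonatal images use ("GM", "WM", "CSF").
    """
    if n_classes != 3:
        raise ParameterError("afcm_segment supports n_classes == 3")
    if sorted(class_order) != sorted(TISSUE_CLASSES):
        raise ParameterError(f"class_order must permute {TISSUE_CLASSES}")
    m = float(fuzziness)
    if m <= 1:
        raise ParameterError("fuzziness must be > 1")
    y = np.asarray(vol.data, dtype=np.float64)[mask]
    if len(np.unique(y)) < n_classes:
        raise DegenerateInputError(
            f"fewer than {n_classes} distinct intensities inside mask")
    gain = np.ones(mask.sum(), dtype=np.float64)
    centers = np.quantile(y, np.linspace(0.1, 0.9, n_classes))
    sigma_vox = [gain_smoothness_mm / s for s in vol.spacing]

    def objective(u, c, g):
        d2 = (y[None, :] - g[None, :] * c[:, None]) ** 2
        return float(np.sum(u**m * d2))

    def memberships(c, g):
        d2 = (y[None, :] - g[None, :] * c[:, None]) ** 2
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        return inv / inv.sum(axis=0, keepdims=True)

    history: list[float] = []
    u = memberships(centers, gain)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        centers = (um * (gain * y)[None, :]).sum(axis=1) / \
                  np.maximum((um * (gain**2)[None, :]).sum(axis=1), 1e-12)
        u = memberships(centers, gain)
        if estimate_gain:
            # pointwise LS gain, smoothed in log domain over the mask
            num = (u**m * centers[:, None] * y[None, :]).sum(axis=0)
            den = np.maximum((u**m * (centers**2)[:, None]).sum(axis=0), 1e-12)
            g_raw = np.clip(num / den, 1e-3, 1e3)
            logg = np.zeros(mask.shape)
            logg[mask] = np.log(g_raw)
            mimg = mask.astype(np.float64)
            sm = ndimage.gaussian_filter(logg * mimg, sigma_vox, mode="reflect")
            den_m = ndimage.gaussian_filter(mimg, sigma_vox, mode="reflect")
            smoothed = np.where(den_m > 1e-8, sm / np.maximum(den_m, 1e-8), 0.0)
            g_new = np.exp(smoothed[mask] - smoothed[mask].mean())
            u_new = memberships(centers, g_new)
            if objective(u_new, centers, g_new) <= objective(u, centers, gain):
                gain, u = g_new, u_new
        obj = objective(u, centers, gain)
        if history and history[-1] - obj < tol * max(abs(history[-1]), 1e-12):
            history.append(obj)
            converged = True
            break
        history.append(obj)

    # order classes by ascending centroid, then map to tissue names
    order = np.argsort(centers, kind="stable")
    name_for_rank = {class_order[r]: order[r] for r in range(n_classes)}
    stack = np.zeros((3,) + mask.shape, dtype=np.float32)
    for ci, name in enumerate(TISSUE_CLASSES):
        comp = np.zeros(mask.shape, dtype=np.float32)
        comp[mask] = u[name_for_rank[name]]
        stack[ci] = comp
    soft = TissueMaps.from_stack(stack, mask, vol.affine.copy())
    ordered = centers[order]
    model = GaussianMixtureSpec({
        class_order[r]: [(1.0, float(ordered[r]), float(max(np.var(y), 1e-6)))]
        for r in range(n_classes)
    })
    res = SegmentationResult.from_soft(soft, model, converged, it, history)
    return res


# ---------------------------------------------------------------------------
# Prior-guided EM segmentation


def _init_mixture_from_priors(y: np.ndarray, prior: np.ndarray,
                              n_components: dict[str, int]) -> GaussianMixtureSpec:
    """Moment initialisation: per class, prior-weighted quantile means and
    the prior-weighted variance shared across components."""
    comps: dict[str, list[tuple[float, float, float]]] = {}
    for ci, name in enumerate(TISSUE_CLASSES):
        w = prior[ci]
        wsum = w.sum()
        if wsum <= 0:
            mu, var = float(y.mean()), float(max(y.var(), 1e-6))
            comps[name] = [(1.0, mu, var)] * max(n_components.get(name, 1), 1)
            continue
        mu = float((w * y).sum() / wsum)
        var = float(max((w * (y - mu) ** 2).sum() / wsum, 1e-6))
        k = max(n_components.get(name, 1), 1)
        if k == 1:
            comps[name] = [(1.0, mu, var)]
        else:
            # spread component means across prior-weighted quantiles
            order = np.argsort(y, kind="stable")
            cw = np.cumsum(w[order])
            cw /= cw[-1]
            qs = np.linspace(0.2, 0.8, k)
            means = [float(y[order][np.searchsorted(cw, q)]) for q in qs]
            comps[name] = [(1.0 / k, mk, var) for mk in means]
    return GaussianMixtureSpec(comps)


def prior_guided_segment(vol: Volume, priors: TissueMaps,
                         mix: GaussianMixtureSpec | dict[str, int] | None = None,
                         prior_relax: float = 0.05, tol: float = 1e-6,
                         max_iter: int = 50,
                         var_floor: float = 1e-4) -> SegmentationResult:
    """EM segmentation with spatially varying tissue priors.

    The class posterior is proportional to the relaxed prior times the
    class likelihood, where each class likelihood is its own Gaussian
    mixture (multiple components per class cover heterogeneous tissue such
    as myelinated vs unmyelinated WM). The relaxed prior is
    (1 - prior_relax) * prior + prior_relax * uniform; with prior_relax 0
    a one-hot prior therefore pins the posterior to the prior regardless
    of intensity. The log-likelihood is non-decreasing over EM updates.

    ``mix`` may be a full :class:`GaussianMixtureSpec`, a component-count
    dict like ``{"CSF": 1, "GM": 1, "WM": 2}`` (moment-initialised from
    the priors), or None (one component per class).
    """
    if vol.data.shape != priors.mask.shape:
        raise SpaceError("priors must live on the volume grid")
    mask = priors.mask
    prior_stack = priors.stack.astype(np.float64)[:, mask]
    if (prior_stack.sum(axis=0) <= 1e-12).any():
        raise ParameterError("priors sum to 0 at some masked voxels")
    prior_stack /= prior_stack.sum(axis=0, keepdims=True)
    y = np.asarray(vol.data, dtype=np.float64)[mask]
    relaxed = (1.0 - prior_relax) * prior_stack + prior_relax / 3.0

    if mix is None or isinstance(mix, dict):
        counts = mix if isinstance(mix, dict) else GaussianMixtureSpec.counts()
        mix = _init_mixture_from_priors(y, prior_stack, counts)
    comps = {k: list(v) for k, v in mix.components.items()}
    scale = float(max(y.std(), 1e-6))

    def loglik_and_resp():
        # joint responsibilities over (class, component)
        logp = []
        keys = []
        for ci, name in enumerate(TISSUE_CLASSES):
            for (w, mu, var) in comps[name]:
                var = max(var, var_floor * scale**2)
                lp = (np.log(np.maximum(relaxed[ci], 1e-300)) + np.log(max(w, 1e-300))
                      - 0.5 * np.log(2 * np.pi * var)
                      - 0.5 * (y - mu) ** 2 / var)
                logp.append(lp)
                keys.append(ci)
        L = np.stack(logp)
        mx = L.max(axis=0)
        lse = mx + np.log(np.exp(L - mx).sum(axis=0))
        resp = np.exp(L - lse)
        return float(lse.sum()), resp, np.array(keys)

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, resp, keys = loglik_and_resp()
        if history and ll - history[-1] < tol * abs(history[-1] + 1e-12) and \
                ll >= history[-1] - 1e-9:
            history.append(ll)
            converged = True
            break
        history.append(ll)
        # M-step
        row = 0
        for ci, name in enumerate(TISSUE_CLASSES):
            k = len(comps[name])
            r_class = resp[row:row + k]
            tot_class = r_class.sum()
            new = []
            for j in range(k):
                r = r_class[j]
                rs = r.sum()
                if rs < 1e-9:
                    new.append(comps[name][j])
                    continue
                mu = float((r * y).sum() / rs)
                var = float(max((r * (y - mu) ** 2).sum() / rs,
                                var_floor * scale**2))
                w = float(rs / max(tot_class, 1e-12))
                new.append((max(w, 1e-9), mu, var))
            wsum = sum(w for w, _, _ in new)
            comps[name] = [(w / wsum, mu, var) for w, mu, var in new]
            row += k
    _, resp, keys = loglik_and_resp()
    stack = np.zeros((3,) + mask.shape, dtype=np.float32)
    for ci in range(3):
        comp = np.zeros(mask.shape, dtype=np.float32)
        comp[mask] = resp[keys == ci].sum(axis=0)
        stack[ci] = comp
    soft = TissueMaps.from_stack(stack, mask, vol.affine.copy())
    model = GaussianMixtureSpec({k: list(v) for k, v in comps.items()})
    return SegmentationResult.from_soft(soft, model, converged, it, history)


# ---------------------------------------------------------------------------
# Joint longitudinal registration-segmentation


def joint_longitudinal_segment(
    early_vol: Volume,
    late_vol: Volume,
    late_result: SegmentationResult,
    mix: GaussianMixtureSpec | dict[str, int] | None = None,
    max_outer: int = 5,
    dice_tol: float = 1e-3,
    prior_relax: float = 0.3,
    schedule=((4, 0.3, 2), (2, 0.3, 2), (1, 0.3, 2)),
    affine_levels: int = 2,
) -> tuple[SegmentationResult, DeformationField]:
    """Iterated registration-segmentation across a longitudinal pair.

    The mature (late) segmentation is first affine-aligned to the early
    image on intensities; then the loop alternates (a) deformable
    registration of the aligned late segmentation onto the current early
    segmentation and (b) prior-guided segmentation of the early image with
    the warped late tissue maps as priors, until the mean per-class Dice
    between consecutive early segmentations changes by less than
    ``dice_tol`` (or ``max_outer`` passes). Returns the final early
    segmentation and the late->early pull-back field.

    The deformable step only composes updates that do not lower its
    internal segmentation overlap, so the loop can never return priors
    less aligned than its affine initialisation in that measure; on
    anatomies whose cross-age change is nearly affine the loop converges
    in one pass to the affine solution.
    """
    aff = affine_register(late_vol, early_vol, levels=affine_levels)
    space = early_vol.space
    aff_field = affine_to_field(aff, space)
    late_soft_aligned = warp(late_result.soft, aff_field)
    priors = _soften_priors(late_soft_aligned)
    seg = prior_guided_segment(early_vol, priors, mix, prior_relax=prior_relax)
    total = aff_field
    prev_hard = seg.hard.data
    for _ in range(max_outer):
        delta = deformable_register(late_soft_aligned, seg.soft,
                                    schedule=schedule)
        total = compose(aff_field, delta)
        priors = _soften_priors(warp(late_soft_aligned, delta))
        seg = prior_guided_segment(early_vol, priors, mix,
                                   prior_relax=prior_relax)
        d = _mean_class_dice(seg.hard.data, prev_hard)
        prev_hard = seg.hard.data
        if 1.0 - d < dice_tol:
            break
    extent = min(d_ * s_ for d_, s_ in zip(space.dims, space.spacing))
    if float(total.magnitude_mm().mean()) > extent / 4:
        from .errors import DivergenceError
        raise DivergenceError("longitudinal registration diverged")
    return seg, total


def _soften_priors(tm: TissueMaps, fwhm_vox: float = 1.5) -> TissueMaps:
    """Slightly blur warped tissue maps before using them as priors, so a
    hard one-hot map still admits boundary uncertainty."""
    sig = fwhm_vox / (2 * np.sqrt(2 * np.log(2)))
    stack = np.stack([
        ndimage.gaussian_filter(tm.maps[k].astype(np.float64), sig,
                                mode="nearest")
        for k in TISSUE_CLASSES])
    mask = tm.mask | (stack.sum(axis=0) > 0.5)
    return TissueMaps.from_stack(stack.astype(np.float32), mask, tm.affine.copy())


def qc_volume_fractions(seg: SegmentationResult,
                        bounds: dict[str, tuple[float, float]] | None = None
                        ) -> dict[str, float | bool]:
    """Automated stand-in for visual QC: flag segmentations whose tissue
    volume fractions leave the configured bounds."""
    bounds = bounds or {"CSF": (0.02, 0.6), "GM": (0.1, 0.8), "WM": (0.05, 0.7)}
    mask = seg.soft.mask
    total = max(int(mask.sum()), 1)
    out: dict[str, float | bool] = {}
    ok = True
    for i, name in enumerate(TISSUE_CLASSES):
        frac = float((seg.hard.data == i + 1).sum() / total)
        out[f"{name}_fraction"] = frac
        lo, hi = bounds[name]
        ok &= lo <= frac <= hi
    out["pass"] = ok
    return out
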