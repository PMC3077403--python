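"""Pairwise transformation machinery.

This module holds the affine registration used for rough alignment, the
feature-based deformable registration (attribute vectors on segmented
images -> driving voxels -> sparse correspondences -> thin-plate-spline
densification), the low-frequency DCT-basis normalisation used by the
evaluation protocol, and the deformation-field algebra (warp, compose,
invert, mean).

Field convention (package-wide): displacement fields are pull-back fields
living on the FIXED/target grid; warping image I by field u samples
I(x + u(x)) at every target voxel x, with displacements in millimetres
along the world axes. ``compose(f, g)`` returns the field whose warp
equals "warp by f, then warp the result by g"; its point map is
T_f o T_g with T_u(x) = x + u(x).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .errors import (
    DivergenceError,
    InversionError,
    ParameterError,
    SingularSystemError,
    SpaceError,
)
from .preprocess import gaussian_smooth_fwhm
from .volumes_io import (
    DeformationField,
    LabelVolume,
    SpaceDef,
    TISSUE_CLASSES,
    TissueMaps,
    Volume,
)

__all__ = [
    "AffineTransform",
    "FeatureVolume",
    "SparseCorrespondences",
    "DCTWarp",
    "affine_register",
    "apply_affine",
    "affine_to_field",
    "extract_features",
    "select_driving_voxels",
    "detect_correspondences",
    "tps_interpolate",
    "deformable_register",
    "dct_normalise",
    "dct_basis",
    "warp",
    "compose",
    "invert",
    "mean_field",
    "EDGE_NONE",
    "EDGE_NAMES",
]

# ---------------------------------------------------------------------------
# Affine transforms


@dataclass
class AffineTransform:
    """12-parameter affine: translation (mm), rotation (rad), scale, shear.

    ``matrix`` is the equivalent 4x4 world-to-world map used for pull-back
    resampling: an output (fixed-space) world point x is sampled from the
    moving image at matrix @ x. Identity parameters give the identity map.
    """

    translation: np.ndarray
    rotation: np.ndarray
    scale: np.ndarray
    shear: np.ndarray
    center: np.ndarray

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls(np.zeros(3), np.zeros(3), np.ones(3), np.zeros(3),
                   np.asarray(center, dtype=float))

    @classmethod
    def from_params(cls, p: np.ndarray, center) -> "AffineTransform":
        p = np.asarray(p, dtype=float)
        return cls(p[0:3], p[3:6], np.exp(p[6:9]), p[9:12],
                   np.asarray(center, dtype=float))

    @property
    def params(self) -> np.ndarray:
        """Flat parameter vector (log-scales for the scale block)."""
        return np.concatenate([self.translation, self.rotation,
                               np.log(self.scale), self.shear])

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)],
                       [0, np.sin(rx), np.cos(rx)]])
        Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0],
                       [-np.sin(ry), 0, np.cos(ry)]])
        Rz = np.array([[np.cos(rz), -np.sin(rz), 0],
                       [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
        Sh = np.eye(3)
        Sh[0, 1], Sh[0, 2], Sh[1, 2] = self.shear
        A = Rx @ Ry @ Rz @ Sh @ np.diag(self.scale)
        M = np.eye(4)
        M[:3, :3] = A
        # rotate/scale about ``center``, then translate
        M[:3, 3] = self.center - A @ self.center + self.translation
        if np.linalg.det(A) <= 0:
            raise ParameterError("affine transform has non-positive determinant")
        return M

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        M = self.matrix
        return pts @ M[:3, :3].T + M[:3, 3]


def apply_affine(vol, t: AffineTransform, out_space: SpaceDef | None = None,
                 order: int = 1):
    """Resample a Volume/LabelVolume through an AffineTransform (pull-back:
    output world point x is sampled from the input at t.matrix @ x)."""
    space = out_space if out_space is not None else vol.space
    M = t.matrix
    in_aff = vol.affine
    in_inv = np.linalg.inv(in_aff)
    # voxel(out) -> world(out) -> world(in) -> voxel(in)
    full = in_inv @ M @ space.affine
    if isinstance(vol, LabelVolume):
        out = ndimage.affine_transform(vol.data, full[:3, :3], full[:3, 3],
                                       output_shape=tuple(space.dims), order=0,
                                       mode="constant", cval=0)
        return LabelVolume(out.astype(vol.data.dtype), space.affine,
                           dict(vol.label_table))
    out = ndimage.affine_transform(np.asarray(vol.data, dtype=np.float64),
                                   full[:3, :3], full[:3, 3],
                                   output_shape=tuple(space.dims),
                                   order=order, mode="constant", cval=0.0)
    return Volume(out.astype(np.float32), space.affine)


def affine_to_field(t: AffineTransform, space: SpaceDef) -> DeformationField:
    """Dense pull-back field equivalent to the affine: u(x) = M x - x."""
    idx = np.indices(space.dims).astype(np.float64)
    sp = np.array(space.spacing)
    off = space.affine[:3, 3]
    world = np.stack([idx[i] * sp[i] + off[i] for i in range(3)], axis=-1)
    M = t.matrix
    mapped = world @ M[:3, :3].T + M[:3, 3]
    return DeformationField((mapped - world).astype(np.float32), space)


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sm = ndimage.gaussian_filter(data, factor / 2.0, mode="reflect")
    return sm[::factor, ::factor, ::factor]


def affine_register(moving: Volume, fixed: Volume, levels: int = 3,
                    maxiter: int = 40, min_factor: int = 1) -> AffineTransform:
    """Estimate the 12-parameter affine aligning ``moving`` to ``fixed``
    over a coarse-to-fine pyramid, by Powell minimisation of
    1 - |masked Pearson correlation| (equivalent to SSD after the best
    linear intensity map, so contrast inversions between timepoints are
    tolerated) with soft bounds keeping scales/shears/rotations in a
    plausible range. Deterministic; identical images yield parameters
    within 1e-3 of identity.
    """
    if moving.data.shape != fixed.data.shape:
        raise SpaceError("affine_register expects images on equal grids")
    center = fixed.space.center_world
    scales = np.array([10.0] * 3 + [0.2] * 3 + [0.2] * 3 + [0.2] * 3)
    factors = [2 ** (levels - 1 - i) for i in range(levels)]
    factors = [f for f in factors
               if min(fixed.data.shape) // f >= 8 and f >= min_factor]
    if not factors:
        factors = [1]
    p = np.zeros(12)
    fdat = np.asarray(fixed.data, dtype=np.float64)
    mdat = np.asarray(moving.data, dtype=np.float64)
    for factor in factors:
        f_lo = _downsample(fdat, factor)
        m_lo = _downsample(mdat, factor)
        aff_lo = fixed.affine.copy()
        aff_lo[:3, :3] *= factor
        sp_lo = SpaceDef(
            f_lo.shape,
            tuple(s * factor for s in fixed.space.spacing),
            tuple(min(o // factor, d - 1) for o, d in
                  zip(fixed.space.origin_voxel, f_lo.shape)),
        )
        idx = np.indices(f_lo.shape).astype(np.float64)
        sp = np.array(sp_lo.spacing)
        off = fixed.affine[:3, 3]
        world = np.stack([idx[i] * sp[i] + off[i] for i in range(3)], axis=-1)
        in_inv = np.linalg.inv(aff_lo)
        wmask = f_lo > (f_lo.min() + 0.01 * (f_lo.max() - f_lo.min() + 1e-12))
        fvals = f_lo[wmask] if wmask.any() else f_lo.ravel()
        fvals = fvals - fvals.mean()
        fnorm = np.sqrt((fvals**2).sum()) + 1e-12
        # soft bounds per parameter (mm / rad / log-scale / shear)
        limits = np.array([60.0] * 3 + [0.6] * 3 + [0.4] * 3 + [0.3] * 3)

        def objective(x):
            p_full = x * scales
            t = AffineTransform.from_params(p_full, center)
            try:
                M = t.matrix
            except ParameterError:
                return 1e12
            mapped = world @ M[:3, :3].T + M[:3, 3]
            vox = mapped @ in_inv[:3, :3].T + in_inv[:3, 3]
            samp = ndimage.map_coordinates(
                m_lo, [vox[..., 0], vox[..., 1], vox[..., 2]],
                order=1, mode="constant", cval=0.0)
            mvals = samp[wmask] if wmask.any() else samp.ravel()
            mvals = mvals - mvals.mean()
            mnorm = np.sqrt((mvals**2).sum())
            if mnorm < 1e-12:
                return 1e6
            corr = float((mvals * fvals).sum() / (mnorm * fnorm))
            over = np.maximum(np.abs(p_full) - limits, 0.0)
            val = 1.0 - abs(corr) + 100.0 * float((over**2).sum())
            if not np.isfinite(val):
                raise ParameterError("non-finite affine objective")
            return val

        res = optimize.minimize(objective, p / scales, method="Powell",
                                options={"maxiter": maxiter,
                                         "maxfev": 30 * maxiter,
                                         "xtol": 1e-4, "ftol": 1e-7})
        p = res.x * scales
    return AffineTransform.from_params(p, center)


# ---------------------------------------------------------------------------
# Features

EDGE_NONE = 0
#: Edge categories: boundary pairs of hard labels (0=bg,1=CSF,2=GM,3=WM).
EDGE_NAMES = {0: "none", 1: "CSF-GM", 2: "GM-WM", 3: "CSF-WM", 4: "brain-bg"}
_PAIR_TO_EDGE = {(1, 2): 1, (2, 3): 2, (1, 3): 3,
                 (0, 1): 4, (0, 2): 4, (0, 3): 4}


@dataclass
class FeatureVolume:
    """Per-voxel attribute vectors on a segmented image.

    ``features`` is (X, Y, Z, C) with channel 0 a z-scored pseudo-intensity
    (membership-weighted class index) and channels 1.. the z-scored
    geometric moment invariants (mass, trace, second invariant, determinant
    of the centred second-moment tensor of each tissue's membership within
    a spherical neighbourhood). ``edge_type`` is the categorical boundary
    code; the GMIs are exactly invariant under 90-degree grid rotations.
    """

    features: np.ndarray
    edge_type: np.ndarray
    mask: np.ndarray
    space: SpaceDef
    gmi_slice: slice = dc_field(default_factory=lambda: slice(1, None))


def _ball_offsets(radius: int) -> np.ndarray:
    rng = np.arange(-radius, radius + 1)
    ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = ox**2 + oy**2 + oz**2 <= radius**2
    return np.stack([ox[keep], oy[keep], oz[keep]], axis=1)


def _ball_kernel(radius: int) -> np.ndarray:
    rng = np.arange(-radius, radius + 1)
    ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
    return (ox**2 + oy**2 + oz**2 <= radius**2).astype(np.float64)


def _edge_types(hard: np.ndarray) -> np.ndarray:
    """Dominant differing label pair in the 6-neighbourhood; ties break to
    the smaller edge code. Background (0) voxels carry no edge."""
    counts = np.zeros((5,) + hard.shape, dtype=np.int16)
    for ax in range(3):
        for shift in (1, -1):
            nb = np.roll(hard, shift, axis=ax)
            # roll wraps; invalidate the wrapped slice by copying edge value
            sl = [slice(None)] * 3
            sl[ax] = slice(0, 1) if shift == 1 else slice(-1, None)
            nb[tuple(sl)] = hard[tuple(sl)]
            differ = nb != hard
            lo = np.minimum(hard, nb)
            hi = np.maximum(hard, nb)
            for (a, b), code in _PAIR_TO_EDGE.items():
                counts[code][differ & (lo == a) & (hi == b)] += 1
    edge = np.argmax(counts[1:], axis=0).astype(np.int8) + 1
    edge[counts[1:].max(axis=0) == 0] = EDGE_NONE
    edge[hard == 0] = EDGE_NONE
    return edge


def extract_features(seg, radius_vox: int = 3) -> FeatureVolume:
    """Attribute vectors (pseudo-intensity, edge type, per-tissue GMIs) of
    a segmentation result. ``seg`` needs ``soft`` (TissueMaps) and ``hard``
    (LabelVolume) attributes, or may be a TissueMaps directly."""
    soft = seg if isinstance(seg, TissueMaps) else seg.soft
    hard = soft.hard() if isinstance(seg, TissueMaps) else seg.hard
    dims = hard.data.shape
    if radius_vox < 1 or radius_vox > min(dims) // 8:
        if radius_vox > min(dims) // 8:
            raise ParameterError(
                f"radius_vox {radius_vox} exceeds 1/8 of grid extent {min(dims)}")
        raise ParameterError("radius_vox must be >= 1")
    mask = soft.mask
    edge = _edge_types(hard.data.astype(np.int8))
    kern = _ball_kernel(radius_vox)
    nvox = kern.sum()
    rng = np.arange(-radius_vox, radius_vox + 1, dtype=np.float64)
    ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = [ox * kern, oy * kern, oz * kern]
    channels = []
    # pseudo-intensity: membership-weighted class index
    s = soft.stack.astype(np.float64)
    pseudo = (1 * s[0] + 2 * s[1] + 3 * s[2]) / 3.0
    channels.append(pseudo)
    for ci in range(3):
        p = s[ci]
        M0 = ndimage.convolve(p, kern, mode="constant", cval=0.0)
        mass = M0 / nvox
        mu = [ndimage.convolve(p, o, mode="constant", cval=0.0) for o in offs]
        M2 = {}
        for a in range(3):
            for b in range(a, 3):
                M2[(a, b)] = ndimage.convolve(
                    p, offs[a] * offs[b] / kern.clip(1e-12) * kern,
                    mode="constant", cval=0.0)
        safe = np.where(M0 > 1e-9, M0, 1.0)
        C = np.zeros(dims + (3, 3))
        for a in range(3):
            for b in range(a, 3):
                cab = M2[(a, b)] / safe - (mu[a] / safe) * (mu[b] / safe)
                C[..., a, b] = cab
                C[..., b, a] = cab
        C[M0 <= 1e-9] = 0.0
        tr = np.trace(C, axis1=-2, axis2=-1)
        tr2 = np.trace(C @ C, axis1=-2, axis2=-1)
        second = 0.5 * (tr**2 - tr2)
        det = np.linalg.det(C)
        channels.extend([mass, tr, second, det])
    feats = np.stack(channels, axis=-1).astype(np.float64)
    # z-score continuous channels over the mask
    if mask.any():
        mu_f = feats[mask].mean(axis=0)
        sd_f = feats[mask].std(axis=0)
        sd_f[sd_f < 1e-12] = 1.0
        feats = (feats - mu_f) / sd_f
        feats[~mask] = 0.0
    return FeatureVolume(feats.astype(np.float32), edge, mask, hard.space)


# ---------------------------------------------------------------------------
# Driving voxels and correspondences


def select_driving_voxels(features: FeatureVolume, fraction: float,
                          min_spacing: int = 2) -> np.ndarray:
    """Edge voxels ranked by distinctiveness (norm of the GMI vector plus a
    constant edge bonus); keep the top ``fraction`` then greedily suppress
    points closer than ``min_spacing`` voxels (Chebyshev) to a kept one.
    Returns (N, 3) voxel indices, deterministically ordered."""
    if not (0 < fraction <= 1):
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    cand = (features.edge_type != EDGE_NONE) & features.mask
    if not cand.any():
        raise ParameterError("no edge voxels to select driving voxels from")
    idx = np.argwhere(cand)
    gmi = features.features[..., features.gmi_slice]
    score = np.linalg.norm(gmi[cand], axis=1) + 1.0
    m = int(np.ceil(fraction * len(idx)))
    # stable ranking: by descending score, ties by lexicographic index
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -score))
    top = idx[order[:m]]
    occupied = np.zeros(features.mask.shape, dtype=bool)
    kept = []
    half = min_spacing - 1
    dims = features.mask.shape
    for p in top:
        lo = np.maximum(p - half, 0)
        hi = np.minimum(p + half + 1, dims)
        if occupied[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].any():
            continue
        occupied[tuple(p)] = True
        kept.append(p)
    return np.array(kept, dtype=np.int64).reshape(-1, 3)


@dataclass
class SparseCorrespondences:
    """Matched point pairs (world mm) with per-pair confidence in (0, 1]."""

    sources: np.ndarray
    targets: np.ndarray
    confidences: np.ndarray

    def __len__(self) -> int:
        return len(self.sources)


def detect_correspondences(driving: np.ndarray, feat_fixed: FeatureVolume,
                           feat_moving: FeatureVolume, radius_vox: int = 4,
                           k: int = 5, sim_floor: float = 0.1,
                           weighted_mean: bool = False,
                           distance_sigma_vox: float | None = None
                           ) -> SparseCorrespondences:
    """For each driving voxel of the moving image, find the k most
    feature-similar voxels of matching edge type within ``radius_vox`` of
    the same location in the fixed image; the target is the (by default
    unweighted) mean location of those candidates. Similarity is
    exp(-||dF||^2 / 2) (channel-mean scaling); candidates are ranked by
    similarity times a Gaussian distance prior of scale
    ``distance_sigma_vox`` (default radius/2), which resolves ties between
    equally similar boundary voxels in favour of small displacements.
    Pairs whose best similarity falls below ``sim_floor`` are dropped, and
    confidence is the mean similarity."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if feat_fixed.mask.shape != feat_moving.mask.shape:
        raise SpaceError("feature volumes must share a grid")
    offs = _ball_offsets(radius_vox)
    off_dist2 = np.sum(offs.astype(np.float64) ** 2, axis=1)
    sig = distance_sigma_vox if distance_sigma_vox is not None else radius_vox / 2.0
    dist_prior = np.exp(-0.5 * off_dist2 / max(sig, 1e-6) ** 2)
    dims = np.array(feat_fixed.mask.shape)
    sp = np.array(feat_fixed.space.spacing)
    origin = feat_fixed.space.affine[:3, 3]
    srcs, tgts, confs = [], [], []
    ffeat = feat_fixed.features
    fedge = feat_fixed.edge_type
    fmask = feat_fixed.mask
    for p in driving:
        e = feat_moving.edge_type[tuple(p)]
        if e == EDGE_NONE:
            continue
        q = p[None, :] + offs
        ok = np.all((q >= 0) & (q < dims[None, :]), axis=1)
        q = q[ok]
        prior = dist_prior[ok]
        qi = (q[:, 0], q[:, 1], q[:, 2])
        sel = (fedge[qi] == e) & fmask[qi]
        q = q[sel]
        prior = prior[sel]
        if len(q) == 0:
            continue
        qi = (q[:, 0], q[:, 1], q[:, 2])
        df = ffeat[qi] - feat_moving.features[tuple(p)][None, :]
        # mean over channels keeps the similarity scale independent of the
        # number of attribute channels
        sim = np.exp(-0.5 * np.mean(df.astype(np.float64) ** 2, axis=1))
        if sim.max() < sim_floor:
            continue
        score = sim * prior
        kk = min(k, len(sim))
        top = np.argsort(-score, kind="stable")[:kk]
        # candidates are near-ties of the best match; averaging clearly
        # inferior matches only drags the target toward the search centre
        top = top[score[top] >= 0.95 * score[top[0]]]
        cand = q[top].astype(np.float64)
        w = sim[top]
        if weighted_mean:
            mean_vox = (cand * w[:, None]).sum(axis=0) / w.sum()
        else:
            mean_vox = cand.mean(axis=0)
        srcs.append(p * sp + origin)
        tgts.append(mean_vox * sp + origin)
        confs.append(float(np.clip(w.mean(), 1e-9, 1.0)))
    if not srcs:
        return SparseCorrespondences(np.zeros((0, 3)), np.zeros((0, 3)),
                                     np.zeros(0))
    return SparseCorrespondences(np.array(srcs), np.array(tgts),
                                 np.array(confs))


# ---------------------------------------------------------------------------
# Thin-plate splines


def tps_interpolate(corr: SparseCorrespondences, space: SpaceDef,
                    ridge: float = 0.0,
                    eval_stride: int = 1) -> DeformationField:
    """Densify sparse correspondences with a 3-D thin-plate spline
    (biharmonic kernel U(r) = r) plus an affine part; one linear solve per
    displacement component, ``ridge`` added to the kernel diagonal. With
    ridge 0 the field reproduces every control displacement exactly.

    ``eval_stride`` > 1 evaluates the spline on a strided subgrid and
    trilinearly upsamples — a speed/accuracy trade used for intermediate
    registration updates that are smoothed afterwards anyway; the default
    1 keeps the exact-interpolation contract."""
    pts = np.asarray(corr.sources, dtype=np.float64)
    disp = np.asarray(corr.targets, dtype=np.float64) - pts
    n = len(pts)
    if n < 4:
        raise SingularSystemError(f"TPS needs >= 4 control points, got {n}")
    if len(np.unique(pts, axis=0)) != n:
        raise SingularSystemError("TPS control points must be unique")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 3:
        raise SingularSystemError("TPS control points are coplanar/collinear")
    K = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    P = np.hstack([np.ones((n, 1)), pts])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K + ridge * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = disp
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(f"TPS system singular: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise SingularSystemError("TPS solve produced non-finite weights")
    w, a = sol[:n], sol[n:]
    sp = np.array(space.spacing)
    off = space.affine[:3, 3]
    stride = max(int(eval_stride), 1)
    axes = [np.arange(0, space.dims[i] + stride - 1, stride)[:, None] * sp[i]
            + off[i] for i in range(3)]
    axes = [np.minimum(ax, (space.dims[i] - 1) * sp[i] + off[i])
            for i, ax in enumerate(axes)]
    gx, gy, gz = np.meshgrid(*[a.ravel() for a in axes], indexing="ij")
    flat = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    out = flat @ a[1:] + a[0]  # affine part
    chunk = 65536
    for start in range(0, len(flat), chunk):
        sl = slice(start, start + chunk)
        d = np.linalg.norm(flat[sl, None, :] - pts[None, :, :], axis=-1)
        out[sl] += d @ w
    coarse = out.reshape(gx.shape + (3,))
    if stride == 1:
        return DeformationField(coarse.astype(np.float32), space)
    # trilinear upsample of the strided evaluation back to the full grid
    idx = np.indices(space.dims).astype(np.float64)
    coords = []
    for i in range(3):
        src = (axes[i].ravel() - off[i]) / sp[i]  # strided voxel positions
        coords.append(np.interp(idx[i].ravel(), src,
                                np.arange(len(src))).reshape(space.dims))
    dense = np.stack([
        ndimage.map_coordinates(coarse[..., c], coords, order=1,
                                mode="nearest")
        for c in range(3)], axis=-1)
    return DeformationField(dense.astype(np.float32), space)


# ---------------------------------------------------------------------------
# Field algebra


def _same_space(a: SpaceDef, b: SpaceDef) -> bool:
    return (a.dims == b.dims and
            np.allclose(a.spacing, b.spacing) and
            a.origin_voxel == b.origin_voxel)


def warp(obj, f: DeformationField, interp: str | None = None):
    """Pull-back warp of a Volume, LabelVolume, TissueMaps or ndarray by
    field ``f``: output(x) = input(x + u(x)). Trilinear for intensities
    and probabilities (renormalised to sum 1 in the warped mask), nearest
    for labels. A zero field returns the input voxel-identically."""
    sp = np.array(f.space.spacing)
    idx = np.indices(f.space.dims).astype(np.float64)
    coords = [idx[i] + f.disp[..., i].astype(np.float64) / sp[i] for i in range(3)]

    def _map(data, order):
        return ndimage.map_coordinates(np.asarray(data, dtype=np.float64),
                                       coords, order=order, mode="constant",
                                       cval=0.0)

    if isinstance(obj, LabelVolume):
        if not _same_space(obj.space, f.space):
            raise SpaceError("label volume and field on different grids")
        out = np.round(_map(obj.data, 0)).astype(obj.data.dtype)
        return LabelVolume(out, obj.affine.copy(), dict(obj.label_table))
    if isinstance(obj, TissueMaps):
        if not _same_space(obj.space, f.space):
            raise SpaceError("tissue maps and field on different grids")
        mask = _map(obj.mask.astype(np.float64), 0) > 0.5
        stack = np.stack([_map(obj.maps[k], 1) for k in TISSUE_CLASSES])
        tm = TissueMaps.from_stack(stack.astype(np.float32), mask, obj.affine.copy())
        return tm
    if isinstance(obj, Volume):
        if not _same_space(obj.space, f.space):
            raise SpaceError("volume and field on different grids")
        order = 0 if interp == "nearest" else 1
        return Volume(_map(obj.data, order).astype(np.float32), obj.affine.copy())
    # raw ndarray on the field grid
    arr = np.asarray(obj)
    if arr.shape[:3] != tuple(f.space.dims):
        raise SpaceError("array and field on different grids")
    order = 0 if interp == "nearest" else 1
    out = _map(arr, order)
    return np.round(out).astype(arr.dtype) if order == 0 and \
        np.issubdtype(arr.dtype, np.integer) else out


def compose(f: DeformationField, g: DeformationField) -> DeformationField:
    """Field of the warp "apply f, then g": (f o g)(x) = f(x + g(x)) + g(x),
    with trilinear lookup of f. The zero field is the neutral element."""
    if not _same_space(f.space, g.space):
        raise SpaceError("cannot compose fields on different grids")
    sp = np.array(f.space.spacing)
    idx = np.indices(f.space.dims).astype(np.float64)
    coords = [idx[i] + g.disp[..., i].astype(np.float64) / sp[i] for i in range(3)]
    out = np.empty_like(g.disp, dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            f.disp[..., c].astype(np.float64), coords, order=1, mode="nearest"
        ) + g.disp[..., c]
    return DeformationField(out.astype(np.float32), f.space)


def invert(f: DeformationField, iters: int = 20,
           fail_residual_voxels: float = 0.5) -> DeformationField:
    """Fixed-point inverse: iterate g(x) <- -f(x + g(x)). Converges for
    smooth fields (max displacement gradient < 1). Raises InversionError
    (with the residual attached) if compose(f, g) still has a mean
    residual above ``fail_residual_voxels``."""
    sp = np.array(f.space.spacing)
    idx = np.indices(f.space.dims).astype(np.float64)
    g = -f.disp.astype(np.float64)
    fd = f.disp.astype(np.float64)
    for _ in range(iters):
        coords = [idx[i] + g[..., i] / sp[i] for i in range(3)]
        new = np.stack([
            -ndimage.map_coordinates(fd[..., c], coords, order=1, mode="nearest")
            for c in range(3)], axis=-1)
        if np.abs(new - g).max() < 1e-3 * sp.min():
            g = new
            break
        g = new
    inv = DeformationField(g.astype(np.float32), f.space)
    resid = compose(f, inv).mean_magnitude_voxels()
    if resid > fail_residual_voxels:
        raise InversionError(
            f"field inversion residual {resid:.3f} voxels exceeds "
            f"{fail_residual_voxels}", residual_voxels=resid)
    return inv


def mean_field(fields: list[DeformationField]) -> DeformationField:
    """Voxelwise arithmetic mean of displacement fields."""
    if not fields:
        raise ParameterError("mean_field needs at least one field")
    space = fields[0].space
    for f in fields[1:]:
        if not _same_space(f.space, space):
            raise SpaceError("mean_field requires a common grid")
    acc = np.zeros_like(fields[0].disp, dtype=np.float64)
    for f in fields:
        acc += f.disp
    return DeformationField((acc / len(fields)).astype(np.float32), space)


# ---------------------------------------------------------------------------
# Deformable registration

#: Default multi-level schedule: (search radius vox, driving fraction, iters)
DEFAULT_SCHEDULE = ((4, 0.2, 2), (2, 0.2, 2), (1, 0.2, 2))


def _mean_class_dice(a: np.ndarray, b: np.ndarray) -> float:
    vals = []
    for lab in (1, 2, 3):
        na, nb = (a == lab).sum(), (b == lab).sum()
        if na + nb == 0:
            vals.append(1.0)
        else:
            inter = ((a == lab) & (b == lab)).sum()
            vals.append(2.0 * inter / (na + nb))
    return float(np.mean(vals))


def deformable_register(moving_seg, fixed_seg,
                        schedule=DEFAULT_SCHEDULE, ridge: float | None = None,
                        gmi_radius: int = 2, k: int = 3,
                        sim_floor: float = 0.05,
                        smooth_update_mm: float = 3.0,
                        tps_stride: int = 2) -> DeformationField:
    """Feature-based deformable registration on segmented images.

    At each level the features of the current warped moving segmentation
    are extracted, driving voxels selected, correspondences detected
    against the fixed features within the level's search radius, and the
    sparse update densified by TPS and composed into the accumulated
    field. Any update that lowers the mean per-class Dice between the
    warped moving and fixed hard segmentations is rejected, so Dice is
    monotone over accepted updates. Returns the moving->fixed pull-back
    field on the fixed grid.
    """
    f_soft = moving_seg if isinstance(moving_seg, TissueMaps) else moving_seg.soft
    x_soft = fixed_seg if isinstance(fixed_seg, TissueMaps) else fixed_seg.soft
    if not _same_space(f_soft.space, x_soft.space):
        raise SpaceError("deformable_register expects a shared grid")
    space = x_soft.space
    fixed_hard = x_soft.hard().data
    moving_hard = f_soft.hard().data
    phi = DeformationField.zero(space)
    best_dice = _mean_class_dice(moving_hard, fixed_hard)
    extent_mm = min(d * s for d, s in zip(space.dims, space.spacing))
    feat_fixed = extract_features(x_soft, gmi_radius)
    for (radius, fraction, iters) in schedule:
        for _ in range(iters):
            warped = warp(f_soft, phi)
            feat_mov = extract_features(warped, gmi_radius)
            try:
                driving = select_driving_voxels(feat_mov, fraction)
            except ParameterError:
                break
            corr = detect_correspondences(driving, feat_fixed, feat_mov,
                                          radius_vox=radius, k=k,
                                          sim_floor=sim_floor)
            if len(corr) < 6:
                continue
            # pull-back update: control points at the fixed-space targets,
            # displacement back to the warped-moving source
            upd_corr = SparseCorrespondences(corr.targets, corr.sources,
                                             corr.confidences)
            rdg = ridge
            if rdg is None:
                d = np.linalg.norm(
                    corr.targets[:, None, :] - corr.targets[None, :, :], axis=-1)
                np.fill_diagonal(d, np.inf)
                rdg = 1e-3 * float(np.median(d.min(axis=1)))
            try:
                delta = tps_interpolate(upd_corr, space, ridge=max(rdg, 1e-6),
                                        eval_stride=tps_stride)
            except SingularSystemError:
                continue
            if smooth_update_mm > 0:
                sig = [smooth_update_mm / s for s in space.spacing]
                sm = np.stack([
                    ndimage.gaussian_filter(delta.disp[..., c], sig,
                                            mode="nearest")
                    for c in range(3)], axis=-1)
                delta = DeformationField(sm, space)
            cand = compose(phi, delta)
            if cand.mean_magnitude_voxels() * max(space.spacing) > extent_mm / 4:
                raise DivergenceError("deformable registration diverged")
            new_hard = warp(f_soft, cand).hard().data
            new_dice = _mean_class_dice(new_hard, fixed_hard)
            if new_dice >= best_dice:
                phi, best_dice = cand, new_dice
    return phi


# ---------------------------------------------------------------------------
# DCT-basis spatial normalisation


@dataclass
class DCTWarp:
    """Low-frequency DCT-basis nonrigid warp plus its affine pre-alignment.

    ``coeffs`` has shape (3,) + basis_dims: one coefficient block per
    displacement direction; the total count is prod(basis_dims) * 3.
    """

    basis_dims: tuple[int, int, int]
    coeffs: np.ndarray
    affine: AffineTransform
    space: SpaceDef

    @property
    def n_coefficients(self) -> int:
        return int(np.prod(self.basis_dims)) * 3


def dct_basis(n: int, k: int) -> np.ndarray:
    """First ``k`` DCT-II basis functions sampled at n points: column m is
    cos(pi (2i + 1) m / (2n))."""
    i = np.arange(n)[:, None]
    m = np.arange(k)[None, :]
    return np.cos(np.pi * (2 * i + 1) * m / (2 * n))


def dct_normalise(subject: Volume, template: Volume,
                  basis_dims=(7, 8, 7), reg_weight: float = 0.01,
                  fwhm_mm: float = 8.0, max_iter: int = 60,
                  affine_levels: int = 2,
                  affine_maxiter: int = 40) -> tuple[DCTWarp, DeformationField]:
    """SPM-style spatial normalisation of ``subject`` to ``template``:
    smooth the subject (8 mm FWHM by default), affine-register, then fit a
    displacement field expanded in the lowest ``basis_dims`` separable
    cosine basis functions per direction by gradient descent (with
    backtracking) on SSD plus a squared-coefficient penalty.

    Returns the DCTWarp and the composed dense subject->template pull-back
    field on the template grid (a point x in template space maps to
    A(x + u_dct(x)) in subject space).
    """
    basis_dims = tuple(int(b) for b in basis_dims)
    space = template.space
    if any(b > d for b, d in zip(basis_dims, space.dims)):
        raise ParameterError(
            f"basis_dims {basis_dims} exceed grid dims {space.dims}")
    if any(b < 1 for b in basis_dims):
        raise ParameterError("basis_dims must be >= 1")
    # Smooth BOTH images with the same kernel: the point of the protocol
    # smoothing is to put subject and reference at a matching level of
    # fuzziness, and fitting a smoothed subject against a sharp template
    # (few-subject averages stay sharp) destabilises the fit around thin
    # bright structures.
    sub = gaussian_smooth_fwhm(subject, fwhm_mm) if fwhm_mm > 0 else subject
    tmpl = gaussian_smooth_fwhm(template, fwhm_mm) if fwhm_mm > 0 else template
    aff = affine_register(sub, tmpl, levels=affine_levels,
                          maxiter=affine_maxiter)
    sub_aff = apply_affine(sub, aff, space)
    S = np.asarray(sub_aff.data, dtype=np.float64)
    T = np.asarray(tmpl.data, dtype=np.float64)
    norm = max(T.max() - T.min(), 1e-12)
    S, T = S / norm, T / norm
    B = [dct_basis(space.dims[i], basis_dims[i]) for i in range(3)]
    sp = np.array(space.spacing)
    idx = np.indices(space.dims).astype(np.float64)
    coeffs = np.zeros((3,) + basis_dims)

    def expand(c):
        # u_d = sum_m c[d, m1, m2, m3] Bx[:,m1] By[:,m2] Bz[:,m3]
        u = np.einsum("dabc,ia,jb,kc->ijkd", c, B[0], B[1], B[2], optimize=True)
        return u

    # Coarse-to-fine in image smoothness: the linearised image-gradient
    # model is only trustworthy within about one smoothing length, so the
    # coefficients are first fitted on extra-smoothed copies and then
    # refined, warm-started, on the original pair.
    S0, T0 = S, T
    x = coeffs.ravel()
    for extra_sigma in (2.0, 0.0):
        if extra_sigma > 0:
            S = ndimage.gaussian_filter(S0, extra_sigma)
            T = ndimage.gaussian_filter(T0, extra_sigma)
        else:
            S, T = S0, T0
        grads = np.gradient(S, *sp)

        def fun(flat, S=S, T=T, grads=grads):
            c = flat.reshape((3,) + basis_dims)
            u = expand(c)
            coords = [idx[i] + u[..., i] / sp[i] for i in range(3)]
            # clamped boundaries: constant-padding switches to cval the
            # moment a coordinate leaves the grid, which makes the
            # objective discontinuous on the boundary planes
            Sw = ndimage.map_coordinates(S, coords, order=1, mode="nearest")
            r = Sw - T
            g = np.stack([
                ndimage.map_coordinates(grads[i], coords, order=1,
                                        mode="nearest")
                for i in range(3)], axis=-1)
            gc = np.einsum("ijkd,ia,jb,kc->dabc", 2.0 * r[..., None] * g,
                           B[0], B[1], B[2], optimize=True)
            gc = gc + 2.0 * reg_weight * c
            obj = float(np.sum(r**2)) + reg_weight * float(np.sum(c**2))
            return obj, gc.ravel()

        # restart on line-search failure: the trilinear objective has
        # gradient kinks at integer coordinates that abort a single
        # L-BFGS run before convergence
        prev = np.inf
        for _ in range(4):
            res = optimize.minimize(fun, x, jac=True, method="L-BFGS-B",
                                    options={"maxiter": max(max_iter // 2, 10),
                                             "ftol": 1e-10})
            x = res.x
            if prev - res.fun < 1e-6 * max(abs(prev), 1e-12):
                break
            prev = res.fun
    coeffs = x.reshape((3,) + basis_dims)
    u = expand(coeffs)
    dct_field = DeformationField(u.astype(np.float32), space)
    total = compose(affine_to_field(aff, space), dct_field)
    return DCTWarp(basis_dims, coeffs, aff, space), total
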