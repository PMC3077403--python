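"""Synthetic longitudinal brain-phantom cohorts with known ground truth.

Each subject is imaged at three ages (0 = neonate, 1 = one-year-old,
2 = two-year-old). The generator works backwards from the anatomically
mature age-2 anatomy: a shared base anatomy (concentric CSF/GM/WM shells
with sinusoidal, sulcus-like boundary perturbations and angular parcels)
is warped by a subject-specific smooth random deformation, and the earlier
ages are obtained by shrinking that anatomy about the grid centre with the
configured growth factors — plus an age-specific smooth non-uniform growth
component, since real brain growth is spatially non-uniform — and swapping
in age-appropriate tissue contrast. The TRUE age-to-2-years deformation
field is known in closed form for every subject (and the remaining
cross-age fields follow by field algebra); with the deformation amplitude
set to zero the growth model reduces to pure isotropic scaling.

Contrast emulates the modality chosen per age in practice: a T2-like
profile at age 0 (CSF brightest, white matter split into a bright
unmyelinated majority and a darker myelinated central core) and T1-like
profiles at ages 1 and 2 (WM brightest). A smooth multiplicative bias
field and additive Gaussian noise complete the image model. The exact
intensity means are configuration defaults, not claims about real MR.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ParameterError
from .volumes_io import (
    DeformationField,
    LabelVolume,
    SpaceDef,
    TissueMaps,
    Volume,
    write_volume,
    write_space,
)

__all__ = [
    "PhantomConfig",
    "PhantomSubject",
    "generate_cohort",
    "generate_smooth_field",
    "base_anatomy",
    "true_cross_age_field",
    "write_cohort",
]

AGES = (0, 1, 2)

#: Default per-age class intensity means. Age 0 is T2-like (CSF brightest;
#: WM split into [unmyelinated, myelinated] means) with the poor GM/WM
#: contrast characteristic of neonatal imaging; age 1 is T1-like with
#: still-reduced contrast, age 2 near-adult T1 contrast.
DEFAULT_CLASS_MEANS = {
    0: {"CSF": [180.0], "GM": [115.0], "WM": [135.0, 90.0]},
    1: {"CSF": [45.0], "GM": [100.0], "WM": [120.0]},
    2: {"CSF": [40.0], "GM": [100.0], "WM": [145.0]},
}


def _default_grid() -> SpaceDef:
    return SpaceDef((64, 64, 64), (2.0, 2.0, 2.0), (32, 32, 32))


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic cohort.

    growth_factors are linear brain scales per age relative to age 2;
    the defaults (0.82, 0.96, 1.0) follow the reported volume trajectory
    of the infant brain (about half the mature volume at birth, ~90% of
    adult volume by age two, growth fast in year one and slower in year
    two). deform_amplitude_mm controls inter-subject anatomical
    variability; noise and bias amplitudes set image degradation.
    """

    n_subjects: int = 10
    grid: SpaceDef = field(default_factory=_default_grid)
    seed: int = 0
    growth_factors: tuple[float, float, float] = (0.82, 0.96, 1.0)
    class_means: dict = field(default_factory=lambda: {
        a: {k: list(v) for k, v in DEFAULT_CLASS_MEANS[a].items()} for a in AGES
    })
    noise_sigma: float = 6.0
    bias_amplitude: float = 0.2
    deform_amplitude_mm: float = 3.0
    deform_smoothness_mm: float = 8.0
    n_parcels: int = 8

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        g = self.growth_factors
        if not (g[0] < g[1] < g[2]):
            raise ConfigError(f"growth_factors must be increasing, got {g}")
        if self.n_parcels < 2:
            raise ConfigError("n_parcels must be >= 2")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.bias_amplitude < 0 or self.bias_amplitude >= 1:
            raise ConfigError("bias_amplitude must be in [0, 1)")
        half_extent = min(d * s for d, s in zip(self.grid.dims, self.grid.spacing)) / 2
        wm_radius_mm = 0.55 * 0.80 * half_extent * g[0]
        if wm_radius_mm < 3 * max(self.grid.spacing):
            raise ConfigError(
                "grid too small to host the three tissue shells at the "
                f"smallest growth factor (WM radius {wm_radius_mm:.1f} mm)"
            )


@dataclass
class PhantomSubject:
    """One subject's ground truth across the three ages.

    Keys of the per-age dicts are the age tags 0, 1, 2. ``true_fields``
    maps (i, j) pairs to the pull-back field that warps the age-j image
    into age-i space; ``bias`` holds the multiplicative gain fields.
    """

    subject_id: int
    images: dict[int, Volume]
    tissues: dict[int, TissueMaps]
    parcellations: dict[int, LabelVolume]
    true_fields: dict[tuple[int, int], DeformationField]
    bias: dict[int, Volume]
    grid: SpaceDef


# ---------------------------------------------------------------------------
# Geometry


def _coords_mm(space: SpaceDef) -> list[np.ndarray]:
    """Per-axis world coordinates relative to the grid centre (mm)."""
    c = (np.array(space.dims) - 1) / 2.0
    return [
        (np.arange(space.dims[i]) - c[i]) * space.spacing[i]
        for i in range(3)
    ]


def base_anatomy(space: SpaceDef, n_parcels: int, brain_fraction: float = 0.80):
    """Shared base anatomy at age-2 scale.

    Returns ``(labels, parcels, myelin_core)``: a 0/1/2/3 tissue label
    array (bg/CSF/GM/WM), an angular GM+WM parcellation, and the boolean
    central-WM "myelinated" core. Shells: WM inside 55% of the (perturbed)
    brain radius, GM from there to 85%, CSF out to the brain surface. The
    boundaries carry sinusoidal angular perturbations to mimic sulci.
    """
    ax = _coords_mm(space)
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    theta = np.arctan2(np.sqrt(X**2 + Y**2), Z)      # polar
    phi = np.arctan2(Y, X)                           # azimuth
    half_extent = min(d * s for d, s in zip(space.dims, space.spacing)) / 2
    R = brain_fraction * half_extent
    # sulcus-like perturbations: low-order on the outer surface, higher
    # frequency on the GM/WM interface (gyral folding analogue)
    surf = 1.0 + 0.05 * np.sin(3 * phi) * np.sin(2 * theta)
    fold = 1.0 + 0.10 * np.sin(6 * phi) * np.sin(4 * theta) \
               + 0.05 * np.cos(5 * phi + 2 * theta)
    r_brain = R * surf
    r_gm = 0.85 * R * surf
    r_wm = 0.55 * R * fold
    labels = np.zeros(space.dims, dtype=np.uint8)
    labels[r <= r_brain] = 1                          # CSF shell
    labels[r <= r_gm] = 2                             # GM shell
    labels[r <= r_wm] = 3                             # WM core
    # angular parcels over GM+WM
    wedge = np.floor((phi + np.pi) / (2 * np.pi) * n_parcels).astype(np.int32)
    wedge = np.clip(wedge, 0, n_parcels - 1)
    parcels = np.where(labels >= 2, wedge + 1, 0).astype(np.int32)
    myelin_core = (labels == 3) & (r <= 0.30 * R)
    return labels, parcels, myelin_core


# ---------------------------------------------------------------------------
# Random smooth fields


def _jacobian_min_det(field: DeformationField) -> float:
    """Min determinant of I + grad(u) by central finite differences
    (voxel units)."""
    u = field.disp_voxels.astype(np.float64)
    J = np.empty(u.shape[:3] + (3, 3))
    for comp in range(3):
        for ax in range(3):
            J[..., comp, ax] = np.gradient(u[..., comp], axis=ax)
    J += np.eye(3)
    return float(np.linalg.det(J).min())


def generate_smooth_field(
    space: SpaceDef,
    amplitude_mm: float,
    smoothness_mm: float,
    seed: int,
    min_jacobian: float = 0.1,
) -> DeformationField:
    """Gaussian-filtered white-noise displacement, rescaled so the maximum
    magnitude equals ``amplitude_mm``; the field is shrunk (by 0.8 steps)
    until the minimum Jacobian determinant exceeds ``min_jacobian`` so it
    stays invertible."""
    if amplitude_mm < 0:
        raise ParameterError("amplitude_mm must be >= 0")
    if amplitude_mm == 0:
        return DeformationField.zero(space)
    rng = np.random.default_rng(seed)
    sigma_vox = [smoothness_mm / s for s in space.spacing]
    disp = np.stack(
        [
            ndimage.gaussian_filter(
                rng.standard_normal(space.dims), sigma_vox, mode="reflect"
            )
            for _ in range(3)
        ],
        axis=-1,
    )
    mag = np.linalg.norm(disp, axis=-1)
    peak = mag.max()
    if peak < 1e-12:
        return DeformationField.zero(space)
    disp = disp * (amplitude_mm / peak)
    f = DeformationField(disp.astype(np.float32), space)
    for _ in range(20):
        if _jacobian_min_det(f) > min_jacobian:
            return f
        f = DeformationField(f.disp * 0.8, space)
    return f


def true_cross_age_field(space: SpaceDef, scale_i: float, scale_j: float) -> DeformationField:
    """Pull-back field on the age-i grid that warps the age-j image into
    age-i space for pure isotropic growth about the grid centre:
    u(x) = (s_j/s_i - 1) (x - c)."""
    ax = _coords_mm(space)
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    fac = scale_j / scale_i - 1.0
    disp = np.stack([fac * X, fac * Y, fac * Z], axis=-1).astype(np.float32)
    return DeformationField(disp, space)


# ---------------------------------------------------------------------------
# Cohort generation


def _warp_nearest(data: np.ndarray, field: DeformationField) -> np.ndarray:
    """Nearest-neighbour pull-back warp of an array on the field's grid."""
    sp = np.array(field.space.spacing)
    idx = np.indices(field.space.dims).astype(np.float32)
    coords = [idx[i] + field.disp[..., i] / sp[i] for i in range(3)]
    return ndimage.map_coordinates(data, coords, order=0, mode="nearest")


def _bias_field(space: SpaceDef, amplitude: float, seed: int) -> np.ndarray:
    """Smooth multiplicative gain in [1-a, 1+a], geometric-mean ~ 1."""
    if amplitude == 0:
        return np.ones(space.dims, dtype=np.float32)
    rng = np.random.default_rng(seed)
    sigma_vox = [d / 4.0 for d in space.dims]  # very low spatial order
    f = ndimage.gaussian_filter(rng.standard_normal(space.dims), sigma_vox,
                                mode="reflect")
    f = f / (np.abs(f).max() + 1e-12)
    gain = np.exp(amplitude * f)
    gain /= np.exp(np.mean(np.log(gain)))
    return gain.astype(np.float32)


def generate_subject(cfg: PhantomConfig, subject_id: int, seed: int) -> PhantomSubject:
    base_labels, base_parcels, base_myelin = base_anatomy(cfg.grid, cfg.n_parcels)
    rng = np.random.default_rng(seed)
    sub_seed = int(rng.integers(0, 2**31 - 1))
    subj_field = generate_smooth_field(
        cfg.grid, cfg.deform_amplitude_mm, cfg.deform_smoothness_mm, sub_seed
    )
    labels2 = _warp_nearest(base_labels, subj_field).astype(np.uint8)
    parcels2 = _warp_nearest(base_parcels, subj_field).astype(np.int32)
    myelin2 = _warp_nearest(base_myelin.astype(np.uint8), subj_field).astype(bool)

    g = cfg.growth_factors
    # Growth toward age 2 is modelled as isotropic scaling about the grid
    # centre plus an age-specific smooth non-uniform component (brain
    # growth is spatially non-uniform); the latter scales with the
    # configured deformation amplitude and with how far the age is from
    # maturity, so deform_amplitude 0 leaves a purely isotropic model.
    # M_t(x) = c + (x - c)/scale_t + d_t(x) maps age-t space into the
    # subject's age-2 space; the pull-back field warping the age-2 image
    # into age-t space is therefore u_t = M_t - id in closed form.
    growth_fields: dict[int, DeformationField] = {}
    denom = max(1.0 - g[0] / g[2], 1e-6)
    for age in (0, 1):
        scale = g[age] / g[2]
        amp = cfg.deform_amplitude_mm * (1.0 - scale) / denom
        growth_fields[age] = generate_smooth_field(
            cfg.grid, amp, cfg.deform_smoothness_mm,
            int(rng.integers(0, 2**31 - 1)))

    ax = _coords_mm(cfg.grid)
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    centred = np.stack([X, Y, Z], axis=-1).astype(np.float32)

    def age_to_2_field(age: int) -> DeformationField:
        scale = g[age] / g[2]
        disp = (1.0 / scale - 1.0) * centred
        if age in growth_fields:
            disp = disp + growth_fields[age].disp
        return DeformationField(disp.astype(np.float32), cfg.grid)

    images: dict[int, Volume] = {}
    tissues: dict[int, TissueMaps] = {}
    parcs: dict[int, LabelVolume] = {}
    biases: dict[int, Volume] = {}
    aff = cfg.grid.affine
    parcel_table = {i + 1: f"parcel_{i + 1}" for i in range(cfg.n_parcels)}
    for age in AGES:
        if age == 2:
            lab, par = labels2.copy(), parcels2.copy()
            mye = myelin2.copy()
        else:
            u = age_to_2_field(age)
            lab = _warp_nearest(labels2, u).astype(np.uint8)
            par = _warp_nearest(parcels2, u).astype(np.int32)
            mye = _warp_nearest(myelin2.astype(np.uint8), u).astype(bool)
        par[lab < 2] = 0  # parcels only on GM/WM
        means = cfg.class_means[age]
        img = np.zeros(cfg.grid.dims, dtype=np.float64)
        img[lab == 1] = means["CSF"][0]
        img[lab == 2] = means["GM"][0]
        wm_means = means["WM"]
        if len(wm_means) >= 2:
            img[(lab == 3) & ~mye] = wm_means[0]
            img[(lab == 3) & mye] = wm_means[1]
        else:
            img[lab == 3] = wm_means[0]
        gain = _bias_field(cfg.grid, cfg.bias_amplitude,
                           int(rng.integers(0, 2**31 - 1)))
        img = img * gain
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
        img[lab == 0] = 0.0  # phantoms carry no skull/background signal
        labvol = LabelVolume(lab, aff, {1: "CSF", 2: "GM", 3: "WM"})
        images[age] = Volume(img.astype(np.float32), aff)
        tissues[age] = TissueMaps.from_hard(labvol)
        parcs[age] = LabelVolume(par, aff, dict(parcel_table))
        biases[age] = Volume(gain, aff)

    # true cross-age fields: (i, j) warps the age-j image into age-i space
    # (point map age-i -> age-j). (t, 2) is closed-form; the rest follow by
    # field algebra (numerical inversion of smooth fields).
    from .registration import compose as _compose, invert as _invert

    fields: dict[tuple[int, int], DeformationField] = {}
    fields[(0, 2)] = age_to_2_field(0)
    fields[(1, 2)] = age_to_2_field(1)
    fields[(2, 0)] = _invert(fields[(0, 2)], iters=40)
    fields[(2, 1)] = _invert(fields[(1, 2)], iters=40)
    fields[(0, 1)] = _compose(fields[(2, 1)], fields[(0, 2)])
    fields[(1, 0)] = _compose(fields[(2, 0)], fields[(1, 2)])
    return PhantomSubject(subject_id, images, tissues, parcs, fields, biases, cfg.grid)


def generate_cohort(cfg: PhantomConfig) -> list[PhantomSubject]:
    """Deterministically generate ``cfg.n_subjects`` subjects; a pure
    function of the configuration (seed included)."""
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=cfg.n_subjects)
    return [generate_subject(cfg, s, int(seeds[s])) for s in range(cfg.n_subjects)]


def write_cohort(subjects: list[PhantomSubject], out_dir: str) -> None:
    """Write a cohort directory tree of NIfTI files plus a JSON manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"n_subjects": len(subjects), "ages": list(AGES), "subjects": []}
    for s in subjects:
        sd = os.path.join(out_dir, f"sub-{s.subject_id:03d}")
        os.makedirs(sd, exist_ok=True)
        entry = {"id": s.subject_id, "files": {}}
        for age in AGES:
            tag = f"age{age}"
            write_volume(s.images[age], os.path.join(sd, f"{tag}_intensity.nii.gz"))
            write_volume(s.tissues[age].hard(), os.path.join(sd, f"{tag}_tissues.nii.gz"))
            write_volume(s.parcellations[age], os.path.join(sd, f"{tag}_parcels.nii.gz"))
            write_volume(s.bias[age], os.path.join(sd, f"{tag}_bias.nii.gz"))
            entry["files"][tag] = f"sub-{s.subject_id:03d}/{tag}_intensity.nii.gz"
        for (i, j), f in s.true_fields.items():
            write_volume(f, os.path.join(sd, f"field_{i}to{j}.nii.gz"))
        manifest["subjects"].append(entry)
    write_space(subjects[0].grid, os.path.join(out_dir, "space.json"))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
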