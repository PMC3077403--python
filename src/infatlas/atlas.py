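"""Atlas bundles and averaged cross-age correspondences.

An atlas bundle for one age group holds the grayscale template (voxelwise
mean of the aligned subjects), the averaged tissue probability maps, the
majority-vote fused parcellation and the space definition. Cross-age
correspondences between atlas spaces are built per subject by chaining
subject->atlas fields with the subject's longitudinal field, then
averaged over subjects.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np

from .errors import PairingError, ParameterError, SpaceError
from .labeling import majority_vote
from .registration import compose, invert, mean_field
from .volumes_io import (
    DeformationField,
    LabelVolume,
    SpaceDef,
    TISSUE_CLASSES,
    TissueMaps,
    Volume,
    read_space,
    read_volume,
    write_space,
    write_volume,
)

__all__ = ["AtlasBundle", "build_atlas", "longitudinal_atlas_correspondence",
           "save_bundle", "load_bundle"]


@dataclass
class AtlasBundle:
    """Template + TPMs + fused parcellation for one age group."""

    age: int
    template: Volume
    tpms: TissueMaps
    parcellation: LabelVolume
    space: SpaceDef
    n_subjects: int
    provenance: str = ""

    def validate(self) -> None:
        dims = tuple(self.space.dims)
        if self.template.data.shape != dims:
            raise SpaceError("template not on the bundle space")
        if self.tpms.mask.shape != dims:
            raise SpaceError("tpms not on the bundle space")
        if self.parcellation.data.shape != dims:
            raise SpaceError("parcellation not on the bundle space")
        self.tpms.validate()


def build_atlas(warped_intensities: list[Volume],
                warped_tpms: list[TissueMaps],
                warped_parcs: list[LabelVolume],
                space: SpaceDef, age: int = 0,
                provenance: str = "") -> AtlasBundle:
    """Average aligned subjects into an atlas bundle: the template is the
    voxelwise mean intensity, the TPMs the renormalised mean
    probabilities, the parcellation the majority vote."""
    if not warped_intensities:
        raise ParameterError("build_atlas needs at least one subject")
    if not (len(warped_intensities) == len(warped_tpms) == len(warped_parcs)):
        raise ParameterError("inputs must have equal length")
    dims = tuple(space.dims)
    for v in warped_intensities:
        if v.data.shape != dims:
            raise SpaceError("intensity volume not on the atlas space")
    template = Volume(
        np.mean([v.data for v in warped_intensities], axis=0).astype(np.float32),
        space.affine)
    stack = np.mean([t.stack for t in warped_tpms], axis=0)
    mask = stack.sum(axis=0) > 0.5
    tpms = TissueMaps.from_stack(stack.astype(np.float32), mask, space.affine)
    parc = majority_vote(warped_parcs)
    bundle = AtlasBundle(age, template, tpms, parc, space,
                         len(warped_intensities), provenance)
    bundle.validate()
    return bundle


def longitudinal_atlas_correspondence(
    cross_fields: list[DeformationField],
    g_i: list[DeformationField],
    g_j: list[DeformationField],
    mode: str = "mean",
) -> DeformationField:
    """Averaged atlas(i) -> atlas(j) correspondence.

    Per subject s the chained pull-back field is
    Phi_s = compose(invert(g_j_s), compose(f_s, g_i_s)), whose point map
    is T_{g_j}^{-1} o T_f o T_{g_i}: an atlas(i)-space point goes through
    the subject's age-i space, the subject's longitudinal i->j mapping,
    and back into atlas(j) space. (Here f_s is the pull-back field on the
    age-i grid that warps the subject's age-j image into age-i space, and
    g_s warps the subject into its atlas space.) The per-subject chains
    are then averaged voxelwise.
    """
    if not (len(cross_fields) == len(g_i) == len(g_j)):
        raise PairingError(
            "every subject must appear in both age groups "
            f"(got {len(cross_fields)}, {len(g_i)}, {len(g_j)} entries)")
    if not cross_fields:
        raise PairingError("no subjects to average over")
    if mode != "mean":
        raise ParameterError(f"unknown mode {mode!r}")
    phis = []
    for f, gi, gj in zip(cross_fields, g_i, g_j):
        phis.append(compose(invert(gj), compose(f, gi)))
    return mean_field(phis)


# ---------------------------------------------------------------------------
# Bundle persistence: a directory of NIfTI files + JSON metadata


def save_bundle(bundle: AtlasBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_volume(bundle.template, os.path.join(out_dir, "template.nii.gz"))
    for name in TISSUE_CLASSES:
        write_volume(Volume(bundle.tpms.maps[name], bundle.space.affine),
                     os.path.join(out_dir, f"tpm_{name.lower()}.nii.gz"))
    write_volume(bundle.parcellation, os.path.join(out_dir, "parcellation.nii.gz"))
    write_space(bundle.space, os.path.join(out_dir, "space.json"))
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump({"age": bundle.age, "n_subjects": bundle.n_subjects,
                   "provenance": bundle.provenance}, fh, indent=2)


def load_bundle(in_dir: str) -> AtlasBundle:
    space = read_space(os.path.join(in_dir, "space.json"))
    template = read_volume(os.path.join(in_dir, "template.nii.gz"))
    stack = np.stack([
        np.asarray(read_volume(
            os.path.join(in_dir, f"tpm_{n.lower()}.nii.gz")).data)
        for n in TISSUE_CLASSES])
    mask = stack.sum(axis=0) > 0.5
    tpms = TissueMaps.from_stack(stack.astype(np.float32), mask, space.affine)
    parc = read_volume(os.path.join(in_dir, "parcellation.nii.gz"),
                       expect="labels")
    with open(os.path.join(in_dir, "provenance.json")) as fh:
        meta = json.load(fh)
    bundle = AtlasBundle(int(meta["age"]), template, tpms, parc, space,
                         int(meta["n_subjects"]), meta.get("provenance", ""))
    bundle.validate()
    return bundle


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    s = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(s.encode()).hexdigest()[:16]
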