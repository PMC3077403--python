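"""Anatomical labeling (framework step 2).

An adult-style parcellation is brought to every subject through the
subject's own mature (age-2) image acting as a bridge: the donor anatomy
is deformably registered to the bridge segmentation, its parcellation is
warped with nearest-neighbour interpolation, and the result is propagated
to the earlier ages of the same subject with the longitudinal fields from
step 1. The per-subject parcellations of one age group are then fused by
voxel-wise majority voting (plurality, ties to the smallest label id).

The package carries the AAL-compatible label table (116 regions: 45
cerebral volumes of interest per hemisphere plus cerebellar hemispheres
and vermis) as metadata; the donor volume itself is not shipped, and
phantom runs use generated K-parcel donors.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ParameterError, SpaceError
from .registration import (
    affine_register,
    affine_to_field,
    compose,
    deformable_register,
    warp,
)
from .volumes_io import DeformationField, LabelVolume, TissueMaps, Volume

__all__ = ["LabelTable", "aal_label_table", "propagate_via_bridge",
           "propagate_longitudinal", "majority_vote"]


@dataclass(frozen=True)
class LabelTableEntry:
    id: int
    name: str
    hemisphere: str  # L / R / V (vermis)
    lobe: str
    division: str    # cerebrum / cerebellum / vermis


@dataclass
class LabelTable:
    """Ordered region table; ids are unique positive integers."""

    entries: list[LabelTableEntry]

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ParameterError("label ids must be unique")
        if any(i <= 0 for i in ids):
            raise ParameterError("label ids must be positive")
        if any(not e.name for e in self.entries):
            raise ParameterError("label names must be nonempty")

    def __len__(self) -> int:
        return len(self.entries)

    def as_dict(self) -> dict[int, str]:
        return {e.id: e.name for e in self.entries}

    def count(self, hemisphere: str | None = None,
              division: str | None = None) -> int:
        n = 0
        for e in self.entries:
            if hemisphere is not None and e.hemisphere != hemisphere:
                continue
            if division is not None and e.division != division:
                continue
            n += 1
        return n


def aal_label_table() -> LabelTable:
    """The packaged AAL-compatible table: 116 regions, 45 cerebral VOIs
    per hemisphere plus cerebellar hemispheres and vermis."""
    entries = []
    with resources.files("infatlas.data").joinpath("aal116.tsv").open() as fh:
        next(fh)
        for line in fh:
            i, name, hemi, lobe, division = line.rstrip("\n").split("\t")
            entries.append(LabelTableEntry(int(i), name, hemi, lobe, division))
    return LabelTable(entries)


def propagate_via_bridge(donor_parc: LabelVolume, donor_seg,
                         bridge_seg, schedule=((4, 0.05, 2), (2, 0.05, 2)),
                         affine_levels: int = 2) -> LabelVolume:
    """Warp a donor parcellation onto a subject's mature (bridge) anatomy.

    The donor segmentation is registered to the bridge segmentation
    (affine initialisation on a tissue-index proxy image, then deformable
    on the segmentations) and the parcellation follows by nearest-
    neighbour warping, restricted to the bridge brain mask. The output
    label set is a subset of the donor label set.
    """
    d_soft = donor_seg if isinstance(donor_seg, TissueMaps) else donor_seg.soft
    b_soft = bridge_seg if isinstance(bridge_seg, TissueMaps) else bridge_seg.soft
    proxy = lambda s: Volume(1 * s.stack[0] + 2 * s.stack[1] + 3 * s.stack[2],
                             s.affine.copy())
    aff = affine_register(proxy(d_soft), proxy(b_soft), levels=affine_levels)
    aff_field = affine_to_field(aff, b_soft.space)
    delta = deformable_register(warp(d_soft, aff_field), b_soft,
                                schedule=schedule)
    total = compose(aff_field, delta)
    out = warp(donor_parc, total)
    data = out.data.copy()
    data[~b_soft.mask] = 0
    return LabelVolume(data, out.affine, dict(donor_parc.label_table))


def propagate_longitudinal(parc_late: LabelVolume,
                           field_late_to_early: DeformationField) -> LabelVolume:
    """Carry a mature-age parcellation to an earlier age of the same
    subject with the longitudinal field from step 1 (nearest-neighbour;
    label closure holds)."""
    if tuple(parc_late.data.shape) != tuple(field_late_to_early.space.dims):
        raise SpaceError("parcellation and field on different grids")
    return warp(parc_late, field_late_to_early)


def majority_vote(parcs: list[LabelVolume]) -> LabelVolume:
    """Voxel-wise plurality vote over aligned parcellations; ties break to
    the smallest label id, and background (0) participates as a label."""
    if not parcs:
        raise ParameterError("majority_vote needs at least one parcellation")
    shape = parcs[0].data.shape
    table: dict[int, str] = {}
    for p in parcs:
        if p.data.shape != shape:
            raise SpaceError("parcellations must share a grid")
        table.update(p.label_table)
    stack = np.stack([p.data for p in parcs])
    labels = np.unique(stack)
    best_count = np.zeros(shape, dtype=np.int32)
    winner = np.zeros(shape, dtype=parcs[0].data.dtype)
    for lab in labels:  # ascending => strict > keeps the smallest id on ties
        cnt = (stack == lab).sum(axis=0).astype(np.int32)
        better = cnt > best_count
        winner[better] = lab
        best_count[better] = cnt[better]
    present = set(int(v) for v in np.unique(winner)) - {0}
    return LabelVolume(winner, parcs[0].affine.copy(),
                       {k: v for k, v in table.items() if k in present} or table)
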