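"""Unbiased groupwise registration (framework step 3).

All subjects of one age group are aligned simultaneously to a hidden
common space: no subject is singled out as the template. The scheme is
(1) deterministic initial reference selection (the subject with minimum
summed SSD to the others after pairwise affine alignment) and affine
alignment of everyone to it; (2) iterate: form the current mean tissue
maps / intensity, deformably register each subject to the mean
segmentation, then remove the common mode by composing every field with
the inverse of the mean field so the average displacement is driven
toward zero. The outputs are the per-subject subject->common-space
fields and the averaged intensity/tissue images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DivergenceError, InversionError, ParameterError
from .registration import (
    affine_register,
    affine_to_field,
    compose,
    deformable_register,
    invert,
    mean_field,
    warp,
)
from .volumes_io import DeformationField, TISSUE_CLASSES, TissueMaps, Volume

__all__ = ["GroupwiseResult", "groupwise_register", "unbias"]


@dataclass
class GroupwiseResult:
    """Per-subject fields into the common space plus the group averages."""

    fields: list[DeformationField]
    mean_image: Volume
    mean_tpms: TissueMaps
    reference_index: int
    outer_iterations: int


def unbias(fields: list[DeformationField]) -> list[DeformationField]:
    """Remove the common mode of a set of fields: compose each with the
    inverse of their voxelwise mean, so the resulting mean displacement
    magnitude is (strictly) smaller. Fields whose mean is already zero
    are returned unchanged."""
    m = mean_field(fields)
    before = m.mean_magnitude_voxels()
    if before < 1e-9:
        return list(fields)
    try:
        minv = invert(m)
    except InversionError as exc:
        raise InversionError(
            f"cannot unbias: mean-field inversion failed ({exc})",
            residual_voxels=exc.residual_voxels) from exc
    return [compose(f, minv) for f in fields]


def _mean_tpms(softs: list[TissueMaps]) -> TissueMaps:
    stack = np.mean([s.stack for s in softs], axis=0)
    mask = stack.sum(axis=0) > 0.5
    return TissueMaps.from_stack(stack.astype(np.float32), mask,
                                 softs[0].affine.copy())


def groupwise_register(segs: list, intensities: list[Volume],
                       outer_iters: int = 3,
                       schedule=((4, 0.2, 2), (2, 0.2, 2)),
                       affine_levels: int = 2,
                       affine_maxiter: int = 40,
                       selection_maxiter: int = 5,
                       stop_mean_voxels: float = 0.1) -> GroupwiseResult:
    """Simultaneous registration of >= 3 subjects to their hidden common
    space. ``segs`` are SegmentationResults (or TissueMaps); the
    intensities are only averaged, all registration runs on segmentations
    because longitudinal/cross-subject intensity profiles differ.
    Deterministic: the reference rule and all component steps are
    deterministic, so permuting the input order permutes only the output
    list order."""
    n = len(segs)
    if n < 3:
        raise ParameterError(f"groupwise registration needs >= 3 subjects, got {n}")
    if len(intensities) != n:
        raise ParameterError("segs and intensities must pair up")
    softs = [s if isinstance(s, TissueMaps) else s.soft for s in segs]
    space = softs[0].space
    proxies = [Volume((1 * s.stack[0] + 2 * s.stack[1] + 3 * s.stack[2]),
                      s.affine.copy()) for s in softs]

    # canonical internal processing order (content hash): permuting the
    # input order then only permutes the outputs, because every summation
    # and pairing below happens in the same canonical sequence
    import hashlib

    keys = [hashlib.sha256(p.data.astype(np.float32).tobytes()).hexdigest()
            for p in proxies]
    order = sorted(range(n), key=lambda i: (keys[i], i))
    inverse = np.argsort(order)
    softs = [softs[i] for i in order]
    proxies = [proxies[i] for i in order]
    intensities = [intensities[i] for i in order]

    # deterministic reference: min summed SSD after (coarse) pairwise
    # affine; SSD is close to symmetric, so each unordered pair is
    # registered once
    from .registration import apply_affine

    ssd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t = affine_register(proxies[i], proxies[j], levels=2,
                                maxiter=selection_maxiter, min_factor=2)
            moved = apply_affine(proxies[i], t)
            d = moved.data - proxies[j].data
            ssd[i, j] = ssd[j, i] = float(np.mean(d**2))
    ref = int(np.argmin(ssd.sum(axis=0)))

    fields: list[DeformationField] = []
    for i in range(n):
        if i == ref:
            fields.append(DeformationField.zero(space))
        else:
            t = affine_register(proxies[i], proxies[ref], levels=affine_levels,
                                maxiter=affine_maxiter)
            fields.append(affine_to_field(t, space))

    it = 0
    for it in range(1, outer_iters + 1):
        warped = [warp(softs[i], fields[i]) for i in range(n)]
        mean_tpms = _mean_tpms(warped)
        for i in range(n):
            try:
                delta = deformable_register(warped[i], mean_tpms,
                                            schedule=schedule)
            except DivergenceError as exc:
                raise DivergenceError(
                    f"subject {i} diverged during groupwise "
                    f"iteration {it}: {exc}") from exc
            fields[i] = compose(fields[i], delta)
        fields = unbias(fields)
        if mean_field(fields).mean_magnitude_voxels() < stop_mean_voxels:
            break

    warped = [warp(softs[i], fields[i]) for i in range(n)]
    mean_tpms = _mean_tpms(warped)
    warped_int = [warp(intensities[i], fields[i]) for i in range(n)]
    mean_img = Volume(np.mean([w.data for w in warped_int], axis=0)
                      .astype(np.float32), space.affine)
    # map back to the caller's subject order
    fields_out = [fields[inverse[i]] for i in range(n)]
    ref_out = int(order[ref])
    return GroupwiseResult(fields_out, mean_img, mean_tpms, ref_out, it)
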