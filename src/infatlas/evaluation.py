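"""Dice overlap and the three atlas-evaluation experiments.

The experiments mirror the standard ways an atlas is consumed, run on a
held-out cohort against several candidate atlas bundles (typically one
age-matched and several age-mismatched ones):

1. Spatial normalisation: subjects are warped to each template with the
   low-frequency DCT normalisation, a voxel-wise majority-voted structure
   image is formed per atlas, and per-subject per-class Dice against the
   voted image measures how consistently the template stacks the cohort.
2. Label propagation: each bundle's parcellation is carried to every age
   of every subject; cross-age label consistency (Dice over labels, pairs
   0v1, 0v2, 1v2) is measured after mapping the maps into one space with
   the averaged longitudinal correspondences.
3. Tissue segmentation: bundle TPMs are warped to each (neonatal) subject
   and used as priors for the prior-guided EM segmentation; Dice against
   the ground-truth labels scores the priors.

Paired two-sided t-tests across subjects (alpha 0.05, no multiplicity
correction by default; Holm available behind a flag) compare atlases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, ParameterError, SpaceError
from .labeling import majority_vote
from .registration import dct_normalise, invert, warp
from .segmentation import prior_guided_segment
from .volumes_io import LabelVolume, TISSUE_CLASSES, TissueMaps, Volume

__all__ = ["dice", "mean_label_dice", "cerebral_volume",
           "experiment_normalization", "experiment_label_propagation",
           "experiment_segmentation", "pairwise_ttests"]


def dice(a: LabelVolume | np.ndarray, b: LabelVolume | np.ndarray,
         label: int) -> float:
    """Dice ratio DR = 2|A and B| / (|A| + |B|) for one label.

    Both empty -> 1.0 (perfect agreement on absence); exactly one empty
    -> 0.0.
    """
    da = a.data if isinstance(a, LabelVolume) else np.asarray(a)
    db = b.data if isinstance(b, LabelVolume) else np.asarray(b)
    if da.shape != db.shape:
        raise SpaceError(f"grid mismatch: {da.shape} vs {db.shape}")
    na = int((da == label).sum())
    nb = int((db == label).sum())
    if na + nb == 0:
        return 1.0
    inter = int(((da == label) & (db == label)).sum())
    return 2.0 * inter / (na + nb)


def mean_label_dice(a: LabelVolume, b: LabelVolume,
                    labels=None) -> float:
    """Mean Dice over the given labels (default: nonzero labels present
    in either input)."""
    if labels is None:
        labels = sorted((set(np.unique(a.data)) | set(np.unique(b.data))) - {0})
    if not labels:
        return 1.0
    return float(np.mean([dice(a, b, int(l)) for l in labels]))


def cerebral_volume(seg, spacing=None) -> float:
    """Cerebral (GM + WM) volume in cm^3 from hard labels."""
    hard = seg.hard if hasattr(seg, "hard") else seg
    data = hard.data if isinstance(hard, LabelVolume) else np.asarray(hard)
    if spacing is None:
        spacing = hard.spacing
    nvox = int(((data == 2) | (data == 3)).sum())
    return nvox * float(np.prod(spacing)) / 1000.0


def pairwise_ttests(table: pd.DataFrame, value: str, group: str,
                    subject: str = "subject", alpha: float = 0.05,
                    holm: bool = False) -> pd.DataFrame:
    """Paired two-sided t-tests of ``value`` between every pair of
    ``group`` levels, paired on ``subject`` (averaged over any remaining
    factors first)."""
    agg = table.groupby([group, subject])[value].mean().unstack(subject)
    names = list(agg.index)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x, y = agg.loc[names[i]], agg.loc[names[j]]
            if len(x) < 2:
                raise ParameterError("paired t-test needs >= 2 subjects")
            t, p = stats.ttest_rel(x, y)
            rows.append({"group_a": names[i], "group_b": names[j],
                         "mean_a": float(x.mean()), "mean_b": float(y.mean()),
                         "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        if holm:
            order = np.argsort(out["p"].to_numpy())
            m = len(out)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * out["p"].iloc[idx])
                adj[idx] = min(running, 1.0)
            out["p_adjusted"] = adj
            out["significant"] = out["p_adjusted"] < alpha
        else:
            out["significant"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# Experiment 1: spatial normalisation


def experiment_normalization(subjects: list[dict], bundles: list,
                             fwhm_mm: float = 4.0, basis_dims=(4, 4, 4),
                             dct_iters: int = 40,
                             affine_maxiter: int = 40) -> dict:
    """Normalise held-out subjects to each bundle's template and score the
    structural consistency of the stacked cohort.

    ``subjects`` is a list of dicts with keys ``image`` (Volume) and
    ``seg`` (SegmentationResult or TissueMaps); all subjects and bundles
    must share one grid. Returns {"table": per-subject rows,
    "summary": mean/sd per atlas and class, "tests": paired t-tests}.
    """
    if len(subjects) < 2:
        raise ParameterError("experiment needs >= 2 held-out subjects")
    rows = []
    for bundle in bundles:
        warped_hards = []
        for s in subjects:
            # dct_normalise smooths subject and template symmetrically
            _, field = dct_normalise(s["image"], bundle.template,
                                     basis_dims=basis_dims, fwhm_mm=fwhm_mm,
                                     max_iter=dct_iters,
                                     affine_maxiter=affine_maxiter)
            soft = s["seg"] if isinstance(s["seg"], TissueMaps) else s["seg"].soft
            warped_hards.append(warp(soft.hard(), field))
        voted = majority_vote(warped_hards)
        for si, wh in enumerate(warped_hards):
            for ci, name in enumerate(TISSUE_CLASSES):
                rows.append({"atlas": getattr(bundle, "age", bundle),
                             "subject": si, "tissue": name,
                             "dice": dice(wh, voted, ci + 1)})
    table = pd.DataFrame(rows)
    summary = table.groupby(["atlas", "tissue"])["dice"].agg(["mean", "std"])
    tests = pairwise_ttests(table, "dice", "atlas")
    return {"table": table, "summary": summary.reset_index(), "tests": tests,
            "metadata": {"test": "paired two-sided t-test", "alpha": 0.05,
                         "direction": "subject fitted to template (forward)"}}


# ---------------------------------------------------------------------------
# Experiment 2: label propagation


def experiment_label_propagation(subjects: list[dict],
                                 bundles_by_age: dict[int, object],
                                 correspondences: dict[tuple[int, int], object],
                                 basis_dims=(4, 4, 4),
                                 dct_iters: int = 40,
                                 fwhm_mm: float = 4.0,
                                 affine_maxiter: int = 40,
                                 fixed_age_bundle: int | None = None) -> dict:
    """Cross-age consistency of atlas-propagated parcellations.

    Each subject dict holds per-age images under ``images[age]``. For
    every subject and age the (age-matched, or the single
    ``fixed_age_bundle``) template is fitted to the subject
    (subject->template DCT fit; the inverse field carries the atlas
    parcellation to the subject — direction recorded in the metadata).
    Each warped map is then sent back to its atlas space with the forward
    fit, cross-age pairs are brought into the earlier age's atlas space
    through the averaged longitudinal correspondences, and label Dice is
    averaged over labels present. Pairs evaluated: (0,1), (0,2), (1,2).
    """
    ages = sorted(bundles_by_age)
    pairs = [(ages[a], ages[b]) for a in range(len(ages))
             for b in range(a + 1, len(ages))]
    for pair in pairs:
        if pair not in correspondences:
            raise PairingError(f"missing correspondence for age pair {pair}")
    rows = []
    for si, s in enumerate(subjects):
        parc_in_atlas: dict[int, LabelVolume] = {}
        for age in ages:
            bundle = bundles_by_age[fixed_age_bundle if fixed_age_bundle
                                    is not None else age]
            img = s["images"][age]
            _, fwd = dct_normalise(img, bundle.template,
                                   basis_dims=basis_dims, fwhm_mm=fwhm_mm,
                                   max_iter=dct_iters,
                                   affine_maxiter=affine_maxiter)
            # best-effort inverse: a poorly matched atlas can yield a
            # barely invertible fit, which then shows up as low Dice
            inv = invert(fwd, fail_residual_voxels=float("inf"))
            parc_subject = warp(bundle.parcellation, inv)
            # back to the age-matched atlas space for comparison
            parc_in_atlas[age] = warp(parc_subject, fwd)
        for (i, j) in pairs:
            moved_j = warp(parc_in_atlas[j], correspondences[(i, j)])
            rows.append({"subject": si, "pair": f"{i}v{j}",
                         "dice": mean_label_dice(parc_in_atlas[i], moved_j)})
    table = pd.DataFrame(rows)
    summary = table.groupby("pair")["dice"].agg(["mean", "std"]).reset_index()
    return {"table": table, "summary": summary,
            "metadata": {"direction": "subject->template fit; inverse "
                                      "applied to carry atlas labels to the "
                                      "subject", "alpha": 0.05}}


# ---------------------------------------------------------------------------
# Experiment 3: atlas-guided neonatal segmentation


def experiment_segmentation(subjects: list[dict], bundles: list,
                            mix=None, prior_relax: float = 0.1,
                            basis_dims=(4, 4, 4), dct_iters: int = 40,
                            fwhm_mm: float = 4.0, affine_maxiter: int = 40,
                            slices: list | None = None) -> dict:
    """Atlas-guided tissue segmentation of (neonatal) subjects.

    Per bundle and subject: fit the subject to the template, invert, warp
    the bundle TPMs to the subject, run prior-guided EM segmentation with
    them, and score per-class Dice against the subject's ground-truth
    labels (``truth`` in each subject dict). ``slices`` optionally
    restricts scoring to a list of (axis, index) planes, mimicking
    protocols that score only selected slices.
    """
    rows = []
    for bundle in bundles:
        if bundle.tpms is None:
            raise ParameterError("bundle lacks TPMs")
        for si, s in enumerate(subjects):
            img = s["image"]
            _, fwd = dct_normalise(img, bundle.template,
                                   basis_dims=basis_dims, fwhm_mm=fwhm_mm,
                                   max_iter=dct_iters,
                                   affine_maxiter=affine_maxiter)
            inv = invert(fwd, fail_residual_voxels=float("inf"))
            priors = warp(bundle.tpms, inv)
            # subject support may exceed the warped prior mask; give the
            # priors full coverage over the subject's own mask
            truth = s["truth"]
            submask = truth.data > 0
            stack = priors.stack
            stack = np.clip(stack, 1e-4, None)
            priors = TissueMaps.from_stack(stack, submask | priors.mask,
                                           priors.affine)
            seg = prior_guided_segment(img, priors, mix,
                                       prior_relax=prior_relax)
            hard = seg.hard.data
            tdat = truth.data
            if slices:
                sel = np.zeros(hard.shape, dtype=bool)
                for ax, index in slices:
                    sl = [slice(None)] * 3
                    sl[ax] = slice(index, index + 1)
                    sel[tuple(sl)] = True
                hard = np.where(sel, hard, -1)
                tdat = np.where(sel, tdat, -1)
            for ci, name in enumerate(TISSUE_CLASSES):
                rows.append({"atlas": getattr(bundle, "age", bundle),
                             "subject": si, "tissue": name,
                             "dice": dice(hard, tdat, ci + 1)})
    table = pd.DataFrame(rows)
    summary = table.groupby(["atlas", "tissue"])["dice"].agg(["mean", "std"])
    tests = pairwise_ttests(table, "dice", "atlas")
    return {"table": table, "summary": summary.reset_index(), "tests": tests,
            "metadata": {"test": "paired two-sided t-test", "alpha": 0.05}}
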