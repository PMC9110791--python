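"""FLAIR lesion-burden masks from intensity thresholds.

Neuroradiologist-style "generous" seed masks around candidate lesions are
refined by an objective intensity criterion: a voxel enters the burden mask
when its FLAIR intensity exceeds 1.02 x the mean cortical FLAIR intensity
of the same subject. The threshold scales with the image, so the rule is
invariant to global intensity scaling. Burden voxels are apportioned across
the white-matter arrival classes (early WM, iWSA) with everything else —
eroded away or excluded as unreliable — counted as unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, GridMismatchError
from .roi import RoiSet

__all__ = ["LesionBurden", "flair_threshold", "lesion_burden"]

#: Multiplier applied to the mean cortical FLAIR intensity.
FLAIR_THRESHOLD_FACTOR = 1.02


@dataclass
class LesionBurden:
    """Lesion burden counts on the (1 mm^3) voxel grid of the FLAIR image."""

    burden_mask: np.ndarray
    total_voxels: int
    n_wm_early: int
    n_iwsa: int
    n_unclassified: int
    proportion_iwsa: float

    def __post_init__(self) -> None:
        assert self.n_wm_early + self.n_iwsa + self.n_unclassified == self.total_voxels


def flair_threshold(flair: np.ndarray, cortex_mask: np.ndarray,
                    factor: float = FLAIR_THRESHOLD_FACTOR) -> float:
    """Lower FLAIR threshold = factor x mean cortical intensity."""
    flair = np.asarray(flair, dtype=float)
    cortex = np.asarray(cortex_mask).astype(bool)
    if flair.shape != cortex.shape:
        raise GridMismatchError("flair and cortex_mask grids differ")
    if not cortex.any():
        raise DomainError("cortex mask is empty")
    mean = float(flair[cortex].mean())
    if mean <= 0:
        warnings.warn("non-positive mean cortical FLAIR intensity; "
                      "threshold degenerate", stacklevel=2)
    return factor * mean


def lesion_burden(flair: np.ndarray, seed_mask: np.ndarray, threshold: float,
                  roi: RoiSet, reliability: np.ndarray | None = None,
                  inclusive: bool = False) -> LesionBurden:
    """Burden mask and per-ROI-class counts inside generous seed masks.

    A seed voxel enters the burden when its intensity is strictly above the
    threshold (``inclusive=True`` switches to >=). ``seed_mask`` may be a
    single boolean volume or a list of them (union taken); an empty seed set
    is a valid lesion-free subject with zero burden. ``reliability`` further
    restricts which burden voxels may count as classified white matter.
    """
    flair = np.asarray(flair, dtype=float)
    if isinstance(seed_mask, (list, tuple)):
        seeds = np.zeros(flair.shape, dtype=bool)
        for m in seed_mask:
            seeds |= np.asarray(m).astype(bool)
    else:
        seeds = np.asarray(seed_mask).astype(bool)
    if seeds.shape != flair.shape:
        raise GridMismatchError("seed mask grid does not match flair")
    above = flair >= threshold if inclusive else flair > threshold
    burden = seeds & above

    iwsa = np.asarray(roi.iwsa).astype(bool)
    early = np.asarray(roi.wm_early).astype(bool)
    if iwsa.shape != flair.shape:
        raise GridMismatchError("roi grids do not match flair")
    if reliability is not None:
        rel = np.asarray(reliability).astype(bool)
        iwsa = iwsa & rel
        early = early & rel
    n_iwsa = int((burden & iwsa).sum())
    n_early = int((burden & early).sum())
    total = int(burden.sum())
    n_uncl = total - n_iwsa - n_early
    prop = n_iwsa / total if total > 0 else 0.0
    return LesionBurden(burden_mask=burden, total_voxels=total,
                        n_wm_early=n_early, n_iwsa=n_iwsa,
                        n_unclassified=n_uncl, proportion_iwsa=prop)
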