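"""TIRF colocalization scoring.

Sparse single-molecule fields are background-dominated, so correlation is
computed only over the brightest pixels: each channel is thresholded at
the top fraction of its pixels (1% by default), the masks are applied to
the original images, and the Pearson correlation of the two masked
channels is taken over the union (or intersection) of the mask supports.
Condition-level Pearson coefficients are compared against a control
condition with Dunnett's many-to-one test at familywise alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ThresholdMask:
    """Top-fraction intensity mask with its cutoff."""

    mask: np.ndarray
    cutoff: float
    n_selected: int
    n_nominal: int


@dataclass
class ColocResult:
    """Pearson colocalization of one image pair."""

    pearson_r: float
    n_pixels_used: int
    threshold_fraction: float
    support: str
    condition: str | None = None
    replicate: str | int | None = None


def threshold_mask(image: np.ndarray, top_fraction: float = 0.01) -> ThresholdMask:
    """Mask of the brightest ``top_fraction`` of pixels (nearest rank).

    Keeps the ceil(top_fraction * n) brightest pixels; every pixel tied at
    the cutoff intensity is kept, so the mask may exceed the nominal count
    under ties.  A constant image has no meaningful top fraction and is
    rejected as degenerate.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    img = np.asarray(image, dtype=float)
    flat = img.ravel()
    n = flat.size
    if n == 0:
        raise ValueError("empty image")
    if np.all(flat == flat[0]):
        raise ValueError("constant image: top-fraction mask is degenerate")
    k = math.ceil(top_fraction * n)
    cutoff = float(np.partition(flat, n - k)[n - k])
    mask = img >= cutoff
    return ThresholdMask(mask=mask, cutoff=cutoff,
                         n_selected=int(mask.sum()), n_nominal=k)


def pearson_coloc(
    pair,
    top_fraction: float = 0.01,
    support: str = "union",
    condition: str | None = None,
    replicate=None,
) -> ColocResult:
    """Pearson correlation of two masked channels over the mask support.

    ``pair`` is any object with ``channel_1``/``channel_2`` arrays (or a
    2-tuple of arrays).  Each channel is thresholded at its top fraction,
    and the correlation of the two channels' intensities is computed over
    the union of the two mask supports (``support='intersection'``
    restricts to pixels bright in both channels; ``support='full'``
    correlates the mask-zeroed images over every pixel, the convention of
    mask-then-correlate image-analysis plugins).

    Union support is sensitive: any bright pixel of either channel
    contributes, and unmatched bright pixels pull r negative, so a fully
    uncorrelated pair scores well below zero.  Intersection and full
    support leave independent channels near r = 0.  All three are monotone
    in the underlying colocalized fraction.
    """
    ch1 = np.asarray(getattr(pair, "channel_1", None) if not isinstance(pair, tuple) else pair[0], float)
    ch2 = np.asarray(getattr(pair, "channel_2", None) if not isinstance(pair, tuple) else pair[1], float)
    if ch1.shape != ch2.shape:
        raise ValueError(f"channel shapes differ: {ch1.shape} vs {ch2.shape}")
    if support not in ("union", "intersection", "full"):
        raise ValueError(f"unknown support {support!r}")
    m1 = threshold_mask(ch1, top_fraction).mask
    m2 = threshold_mask(ch2, top_fraction).mask
    if support == "full":
        sup = np.ones(ch1.shape, dtype=bool)
        v1 = np.where(m1, ch1, 0.0)[sup]
        v2 = np.where(m2, ch2, 0.0)[sup]
    else:
        sup = (m1 | m2) if support == "union" else (m1 & m2)
        v1 = ch1[sup]
        v2 = ch2[sup]
    n_used = int(sup.sum())
    if n_used < 2:
        raise ValueError(f"mask {support} support has {n_used} pixels (<2)")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("zero variance in a masked channel over the support")
    r = float(stats.pearsonr(v1, v2).statistic)
    return ColocResult(pearson_r=r, n_pixels_used=n_used,
                       threshold_fraction=top_fraction, support=support,
                       condition=condition, replicate=replicate)


def compare_to_control(
    groups: Mapping[str, Sequence[float]],
    control: str,
    alpha: float = 0.05,
    random_state=None,
) -> pd.DataFrame:
    """Dunnett many-to-one comparison of conditions against a control.

    Each non-control condition's Pearson coefficients are compared with
    the control's, with the familywise error rate held at ``alpha`` across
    the family of comparisons.  Returns one row per condition with the
    mean difference, adjusted p-value and reject flag.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} absent from groups")
    names = [n for n in groups if n != control]
    if not names:
        raise ValueError("need at least one non-control group")
    samples = [np.asarray(groups[n], float) for n in names]
    ctrl = np.asarray(groups[control], float)
    for label, arr in [(control, ctrl)] + list(zip(names, samples)):
        if len(arr) < 2:
            raise ValueError(f"group {label!r} has <2 observations")
    res = stats.dunnett(*samples, control=ctrl, random_state=random_state)
    ctrl_mean = float(ctrl.mean())
    return pd.DataFrame(
        {
            "condition": names,
            "mean_diff": [float(s.mean()) - ctrl_mean for s in samples],
            "p_adj": np.asarray(res.pvalue, float),
            "reject": np.asarray(res.pvalue, float) < alpha,
        }
    )
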