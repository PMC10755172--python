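"""Hue phenotyping and kernel-level quality control.

Pericarp color is summarized per kernel as the hue angle of the mean RGB of
the axial sampling region (the band excluding the yellow endosperm cap at
the base and the darker tip zone).  Hue comes from the standard RGB->HSV
sector formula scaled to circular degrees; smaller hue means darker, redder
pericarp.  Two IQR-fence filters mirror the quality control applied to real
scans: a per-image fence on kernel length:width ratio and a pooled fence on
each of the R, G, B channel means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KernelColor",
    "kernel_hue",
    "region_mean_color",
    "shape_qc",
    "color_qc",
    "aggregate_line_hue",
    "classify_pigment_by_hue",
]


@dataclass(frozen=True)
class KernelColor:
    """Mean region color of one kernel and its derived hue."""

    mean_r: float
    mean_g: float
    mean_b: float
    hue: float
    n_region_pixels: int
    achromatic: bool = False


def kernel_hue(mean_r: float, mean_g: float, mean_b: float) -> tuple[float, bool]:
    """Hue angle in degrees [0, 360) of an RGB triple, plus achromatic flag.

    Standard HSV sector formula on channel means: with M = max(R,G,B),
    m = min(R,G,B) and d = M - m,

        hue = 60 * ((G-B)/d mod 6)   if M = R
              60 * ((B-R)/d + 2)     if M = G
              60 * ((R-G)/d + 4)     if M = B

    An achromatic input (R = G = B, d = 0) has no defined hue; 0.0 is
    returned with the flag set.
    """
    r, g, b = float(mean_r), float(mean_g), float(mean_b)
    for v in (r, g, b):
        if not 0.0 <= v <= 255.0:
            raise ValueError("RGB channel means must lie in [0, 255]")
    mx = max(r, g, b)
    mn = min(r, g, b)
    d = mx - mn
    if d == 0.0:
        return 0.0, True
    if mx == r:
        h = ((g - b) / d) % 6.0
    elif mx == g:
        h = (b - r) / d + 2.0
    else:
        h = (r - g) / d + 4.0
    return (60.0 * h) % 360.0, False


def region_mean_color(image: np.ndarray, region_mask: np.ndarray) -> KernelColor:
    """Mean R, G, B over a region mask and the resulting hue."""
    if region_mask.sum() == 0:
        raise ValueError("empty region mask")
    px = image[region_mask.astype(bool)]
    mr, mg, mb = (float(px[:, c].mean()) for c in range(3))
    hue, achro = kernel_hue(mr, mg, mb)
    return KernelColor(mr, mg, mb, hue, int(region_mask.sum()), achro)


def _iqr_fences(values: np.ndarray, mult: float) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - mult * iqr, q3 + mult * iqr


def shape_qc(
    kernels: pd.DataFrame, iqr_mult: float = 1.5, min_for_iqr: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image IQR fence on length:width ratio.

    ``kernels`` needs columns ``image_id``, ``kernel_id``, ``length_px``,
    ``width_px``.  Within each image, kernels whose ratio falls outside
    [Q1 - mult*IQR, Q3 + mult*IQR] are removed.  Images with fewer than
    ``min_for_iqr`` kernels pass through unfiltered (fence meaningless) and
    a zero IQR passes everything.  Returns (retained, removal_log).
    """
    if iqr_mult < 0:
        raise ValueError("iqr_mult must be nonnegative")
    kernels = kernels.copy()
    kernels["lw_ratio"] = kernels["length_px"] / kernels["width_px"]
    keep_idx: list[pd.Index] = []
    removed_rows = []
    for image_id, grp in kernels.groupby("image_id", sort=False):
        if len(grp) < min_for_iqr:
            keep_idx.append(grp.index)
            continue
        lo, hi = _iqr_fences(grp["lw_ratio"].to_numpy(), iqr_mult)
        ok = (grp["lw_ratio"] >= lo) & (grp["lw_ratio"] <= hi)
        keep_idx.append(grp.index[ok])
        for _, row in grp[~ok].iterrows():
            removed_rows.append(
                {
                    "image_id": image_id,
                    "kernel_id": row["kernel_id"],
                    "reason": "lw_ratio_outside_iqr_fence",
                    "value": row["lw_ratio"],
                    "fence_lo": lo,
                    "fence_hi": hi,
                }
            )
    retained = kernels.loc[np.concatenate([i.to_numpy() for i in keep_idx])
                           if keep_idx else []]
    log = pd.DataFrame(
        removed_rows,
        columns=["image_id", "kernel_id", "reason", "value", "fence_lo", "fence_hi"],
    )
    return retained.sort_index(), log


def color_qc(
    kernels: pd.DataFrame, iqr_mult: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled IQR fence on each RGB channel mean, across all kernels.

    A kernel is removed when any of mean_r, mean_g, mean_b falls outside the
    pooled 1.5*IQR fence for that channel.  Order-independent by
    construction (fences depend on the pooled distribution only).
    """
    if iqr_mult < 0:
        raise ValueError("iqr_mult must be nonnegative")
    bad = pd.Series(False, index=kernels.index)
    removed_rows = []
    for chan in ("mean_r", "mean_g", "mean_b"):
        lo, hi = _iqr_fences(kernels[chan].to_numpy(), iqr_mult)
        fail = (kernels[chan] < lo) | (kernels[chan] > hi)
        for idx in kernels.index[fail & ~bad]:
            removed_rows.append(
                {
                    "image_id": kernels.at[idx, "image_id"]
                    if "image_id" in kernels
                    else None,
                    "kernel_id": kernels.at[idx, "kernel_id"],
                    "reason": f"{chan}_outside_pooled_iqr_fence",
                    "value": kernels.at[idx, chan],
                    "fence_lo": lo,
                    "fence_hi": hi,
                }
            )
        bad |= fail
    log = pd.DataFrame(
        removed_rows,
        columns=["image_id", "kernel_id", "reason", "value", "fence_lo", "fence_hi"],
    )
    return kernels[~bad], log


def aggregate_line_hue(
    kernels: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Aggregate retained kernels to per-image and then per line x replicate hue.

    ``kernels`` needs ``image_id`` and ``hue``; ``metadata`` maps ``image_id``
    to ``line_id``, ``population_id`` and ``replicate``.  Per-image hue is the
    arithmetic mean over retained kernels (pericarp hues sit far from the
    0/360 wrap, so no circular mean is needed); a line x replicate value is
    the mean over that plot's images.  Images with zero retained kernels are
    excluded with a logged reason.
    """
    warnings: list[str] = []
    per_image = (
        kernels.groupby("image_id")
        .agg(hue=("hue", "mean"), n_kernels=("hue", "size"))
        .reset_index()
    )
    missing = set(metadata["image_id"]) - set(per_image["image_id"])
    for image_id in sorted(missing):
        warnings.append(f"image {image_id}: zero retained kernels, excluded")
    merged = per_image.merge(metadata, on="image_id", how="inner")
    line_table = (
        merged.groupby(["line_id", "population_id", "replicate"])
        .agg(hue=("hue", "mean"), n_kernels=("n_kernels", "sum"),
             n_images=("image_id", "nunique"))
        .reset_index()
    )
    return line_table, warnings


def classify_pigment_by_hue(hue: np.ndarray, threshold: float) -> np.ndarray:
    """Helper 0/1 pigment call from hue (1 = pigmented = hue below threshold).

    The binary pigment class used in segregation analysis is normally a
    visual rating supplied as metadata; this helper is an explicit,
    opt-in substitute for simulated data and is never applied implicitly.
    """
    return (np.asarray(hue, dtype=float) < float(threshold)).astype(int)
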