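"""Serial killing-assay quantification and integrated-value scoring.

The assay co-cultures a T cell product with GFP-expressing tumor cells at
several effector:target (E:T) ratios, re-challenging with fresh tumor every
3 days for 11 rounds (33 days) and imaging every 7 h.  Quantities:

* **% killing** per frame — areas within a round are normalized to that
  round's first (anchor) frame t1: ``100 - (area / area_t1) * 100``.  The
  anchor frame is 0 by construction; net tumor growth gives negative values,
  which are deliberately not clamped so growth penalizes the score.
* **3-day IV** — the per-round integrated value: the sum of % killing over
  all frames of the round.
* **33-day IV** — the sum of the 3-day IVs across rounds; the per-product,
  per-E:T serial-killing score.

A minimal image-quantification step (threshold + pixel count) is provided
for raw grayscale frames; pre-tabulated area tables are accepted directly.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = ["quantify_gfp_area", "percent_killing", "iv3", "iv33", "read_killing_csv"]

_KEYS = ["product", "et_ratio", "round"]


def quantify_gfp_area(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    pixel_size: float = 1.0,
) -> float:
    """Total GFP+ area of a grayscale frame: pixels at/above threshold.

    ``method="otsu"`` picks the threshold automatically (a constant image has
    no foreground and returns 0); ``method="fixed"`` requires ``threshold``.
    ``pixel_size`` converts the count to calibrated units (area scales with
    its square).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    if np.any(image < 0):
        raise ValueError("intensities must be non-negative")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = threshold
    elif method == "otsu":
        if image.max() == image.min():
            return 0.0
        thr = threshold_otsu(image)
        # Otsu places the threshold between classes; count the bright class
        return float((image > thr).sum()) * pixel_size**2
    else:
        raise ValueError(f"unknown method {method!r}")
    return float((image >= thr).sum()) * pixel_size**2


def _check_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"killing table missing columns: {missing}")


def percent_killing(series: pd.DataFrame) -> pd.DataFrame:
    """Per-frame % killing relative to each round's anchor frame.

    Input: long table with columns ``product, et_ratio, round, hours, area``.
    The anchor is the earliest frame of each (product, E:T, round) group.
    Returns the table with ``pct_killing`` added; rounds whose anchor area is
    zero yield NaN and a warning.
    """
    _check_columns(series, _KEYS + ["hours", "area"])
    df = series.sort_values(_KEYS + ["hours"], kind="stable").reset_index(drop=True)
    anchor = df.groupby(_KEYS, sort=False)["area"].transform("first")
    bad = anchor == 0
    if bad.any():
        n_bad = df.loc[bad, _KEYS].drop_duplicates().shape[0]
        warnings.warn(f"{n_bad} round(s) with zero anchor area; % killing undefined", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 - (df["area"] / anchor) * 100.0
    df["pct_killing"] = pct.where(~bad, np.nan)
    return df


def iv3(series: pd.DataFrame, expected_frames: int | None = None) -> pd.DataFrame:
    """3-day integrated value: sum of % killing over each round's frames.

    Accepts either a raw area table (``pct_killing`` computed on the fly) or
    one already carrying ``pct_killing``.  Returns one row per
    (product, et_ratio, round) with column ``iv3``.  Missing frames still sum
    over what is present, with a warning when ``expected_frames`` is given.
    """
    df = series if "pct_killing" in series.columns else percent_killing(series)
    grouped = df.groupby(_KEYS, sort=True)
    out = grouped["pct_killing"].sum(min_count=1).rename("iv3").reset_index()
    if expected_frames is not None:
        short = grouped.size() < expected_frames
        if short.any():
            warnings.warn(
                f"{int(short.sum())} round(s) have fewer than {expected_frames} frames; "
                "IV summed over available frames",
                stacklevel=2,
            )
    return out


def iv33(series: pd.DataFrame, expected_rounds: int = 11) -> pd.DataFrame:
    """33-day integrated value per product and E:T ratio: the sum of 3-day IVs."""
    per_round = series if set(series.columns) >= {"product", "et_ratio", "round", "iv3"} else iv3(series)
    counts = per_round.groupby(["product", "et_ratio"], sort=True)["round"].nunique()
    if (counts < expected_rounds).any():
        warnings.warn(
            f"some series have fewer than {expected_rounds} rounds; 33-day IV summed over available rounds",
            stacklevel=2,
        )
    out = (
        per_round.groupby(["product", "et_ratio"], sort=True)["iv3"]
        .sum(min_count=1)
        .rename("iv33")
        .reset_index()
    )
    return out


def read_killing_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, _KEYS + ["hours", "area"])
    return df
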