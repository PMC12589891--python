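"""Panel-establishment quality control: stain index, titration, FMO variability.

The stain index SI = (MFI_pos - MFI_neg) / (2 * SD_neg) measures how well an
antibody/dilution resolves a positive from a negative population; titration
picks the dilution with the highest SI (ties go to the most dilute, the
cheaper choice).  FMO (fluorescence-minus-one) variability checks panel
consistency across donors: the sample SD of marker-positive frequencies must
stay below 8 percentage points.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StainDistributions",
    "stain_index",
    "select_titration",
    "fmo_variability",
    "FMO_SD_THRESHOLD",
]

FMO_SD_THRESHOLD = 8.0  # percentage points


@dataclass(frozen=True)
class StainDistributions:
    """Summary statistics of the stained positive and negative populations.

    MFI is the arithmetic mean fluorescence intensity (median optional via
    how the summary was computed upstream).
    """

    mfi_positive: float
    mfi_negative: float
    sd_negative: float
    sd_positive: float = float("nan")
    dilution: str = ""

    def __post_init__(self) -> None:
        if self.sd_negative <= 0:
            raise ValueError("sd_negative must be > 0")


def stain_index(d: StainDistributions) -> float:
    """SI = (MFI_positive - MFI_negative) / (2 * SD_negative)."""
    return (d.mfi_positive - d.mfi_negative) / (2.0 * d.sd_negative)


def summarize_stain(
    positive: Sequence[float],
    negative: Sequence[float],
    dilution: str = "",
    statistic: str = "mean",
) -> StainDistributions:
    """Empirical stain summary from raw positive/negative intensity draws."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    center = np.mean if statistic == "mean" else np.median
    return StainDistributions(
        mfi_positive=float(center(pos)),
        mfi_negative=float(center(neg)),
        sd_negative=float(neg.std(ddof=1)),
        sd_positive=float(pos.std(ddof=1)),
        dilution=dilution,
    )


def _dilution_factor(label: str) -> float:
    """Parse '1:200'-style labels to a factor (higher = more dilute)."""
    m = re.fullmatch(r"\s*1\s*:\s*([0-9.]+)\s*", label)
    if m:
        return float(m.group(1))
    try:
        return float(label)
    except ValueError:
        return float("nan")


def select_titration(series: Sequence[StainDistributions]) -> StainDistributions:
    """Pick the dilution with the highest stain index.

    Exact SI ties are broken toward the most dilute preparation (parsed from
    '1:N' labels; unparseable labels fall back to the later entry, on the
    convention that titration series run concentrated to dilute).
    """
    if len(series) == 0:
        raise ValueError("empty titration series")
    sis = np.array([stain_index(d) for d in series])
    best = sis.max()
    tied = [d for d, s in zip(series, sis) if s == best]
    if len(tied) == 1:
        return tied[0]
    factors = [_dilution_factor(d.dilution) for d in tied]
    if not any(np.isnan(f) for f in factors):
        return tied[int(np.argmax(factors))]
    return tied[-1]


def fmo_variability(freqs: pd.DataFrame, threshold: float = FMO_SD_THRESHOLD) -> pd.DataFrame:
    """Per-marker SD of positive-cell frequencies across donors, with pass/fail.

    ``freqs``: markers x donors table of marker-positive fractions in percent.
    Sample SD (ddof = 1); pass when SD < ``threshold`` percentage points.
    Requires at least 2 donors.
    """
    if freqs.shape[1] < 2:
        raise ValueError("FMO variability needs at least 2 donors")
    sd = freqs.std(axis=1, ddof=1)
    return pd.DataFrame({"sd": sd, "pass": sd < threshold})
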