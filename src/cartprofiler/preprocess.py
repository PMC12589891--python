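"""Scaling, acquisition-drift cleaning, and per-sample subsampling.

The preprocessing chain mirrors standard spectral-cytometry practice:
variance-stabilizing arcsinh scaling (``asinh(x / cofactor)``), removal of
acquisition segments whose channel means drift from the rest of the run
(a simplified segment-mean outlier cleaner), and seeded uniform subsampling
to a per-sample event cap so no donor dominates downstream clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from cartprofiler.io import EventTable

__all__ = [
    "ArcsinhTransform",
    "arcsinh_transform",
    "CleaningReport",
    "clean_time_drift",
    "subsample_events",
]

DEFAULT_COFACTOR = 150.0  # conventional for unmixed fluorescence intensities


class ArcsinhTransform(TransformerMixin, BaseEstimator):
    """Per-channel arcsinh scaling ``x -> asinh(x / cofactor)``.

    Stateless sklearn transformer (monotone, odd, order-preserving per
    channel).  ``cofactor`` is a positive scalar applied to every channel or
    a mapping channel -> cofactor; channels absent from the mapping use
    ``default_cofactor``.
    """

    def __init__(
        self,
        cofactor: float | Mapping[str, float] = DEFAULT_COFACTOR,
        default_cofactor: float = DEFAULT_COFACTOR,
    ) -> None:
        self.cofactor = cofactor
        self.default_cofactor = default_cofactor

    def _cofactor_vector(self, columns) -> np.ndarray:
        if isinstance(self.cofactor, Mapping):
            cf = np.array([float(self.cofactor.get(c, self.default_cofactor)) for c in columns])
        else:
            cf = np.full(len(columns), float(self.cofactor))
        if np.any(cf <= 0):
            bad = [c for c, v in zip(columns, cf) if v <= 0]
            raise ValueError(f"cofactors must be > 0; non-positive for {bad}")
        return cf

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            cf = self._cofactor_vector(X.columns)
            return pd.DataFrame(np.arcsinh(X.to_numpy(dtype=float) / cf), columns=X.columns, index=X.index)
        X = np.asarray(X, dtype=float)
        cf = self._cofactor_vector(range(X.shape[1]))
        return np.arcsinh(X / cf)

    def inverse_transform(self, X):
        if isinstance(X, pd.DataFrame):
            cf = self._cofactor_vector(X.columns)
            return pd.DataFrame(np.sinh(X.to_numpy(dtype=float)) * cf, columns=X.columns, index=X.index)
        X = np.asarray(X, dtype=float)
        cf = self._cofactor_vector(range(X.shape[1]))
        return np.sinh(X) * cf


def arcsinh_transform(
    events: EventTable,
    cofactors: float | Mapping[str, float] = DEFAULT_COFACTOR,
    skip_channels: tuple[str, ...] = ("Time",),
) -> EventTable:
    """Arcsinh-scale every marker channel of a raw event table.

    The acquisition-time channel is passed through untouched.  Raises if the
    table is already on the arcsinh scale or a cofactor is non-positive.
    """
    if events.scale_state != "raw":
        raise ValueError(f"expected raw-scale events, got scale_state={events.scale_state!r}")
    tf = ArcsinhTransform(cofactor=cofactors)
    markers = [c for c in events.values.columns if c not in skip_channels]
    out = events.values.copy()
    out[markers] = tf.transform(events.values[markers])
    return events.with_values(out, scale_state="arcsinh")


@dataclass
class CleaningReport:
    """Outcome of the acquisition-drift cleaner."""

    segments_examined: int
    segments_removed: int
    events_removed: int
    removed_segments: list[int] = field(default_factory=list)
    channel_max_abs_z: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "segments_examined": self.segments_examined,
            "segments_removed": self.segments_removed,
            "events_removed": self.events_removed,
            "removed_segments": list(self.removed_segments),
            "channel_max_abs_z": dict(self.channel_max_abs_z),
        }


def clean_time_drift(
    events: EventTable,
    segment_size: int = 500,
    z_threshold: float = 3.0,
    max_removed_fraction: float = 0.3,
    time_channel: str = "Time",
) -> tuple[EventTable, CleaningReport]:
    """Remove acquisition segments whose per-channel mean drifts.

    Events are ordered by the acquisition-time channel and split into
    consecutive segments of ``segment_size``.  For each channel, segment
    means are compared against the distribution of all segment means of that
    channel (robust z via median and MAD, falling back to the sample SD when
    MAD is zero); a segment is removed when any channel exceeds
    ``z_threshold``.  Removal is capped at ``max_removed_fraction`` of
    events, dropping the most aberrant segments first.  A global shift common
    to all segments produces no relative drift and removes nothing.
    """
    if time_channel not in events.values.columns:
        warnings.warn(f"no {time_channel!r} channel; drift cleaning skipped", stacklevel=2)
        return events, CleaningReport(0, 0, 0)

    order = np.argsort(events.values[time_channel].to_numpy(), kind="stable")
    n = len(order)
    n_segments = max(n // segment_size, 1)
    bounds = np.linspace(0, n, n_segments + 1).astype(int)
    segments = [order[bounds[i]:bounds[i + 1]] for i in range(n_segments)]

    channels = [c for c in events.values.columns if c != time_channel]
    X = events.values[channels].to_numpy(dtype=float)
    seg_means = np.vstack([X[idx].mean(axis=0) for idx in segments])  # segments x channels

    med = np.median(seg_means, axis=0)
    mad = np.median(np.abs(seg_means - med), axis=0)
    scale = 1.4826 * mad
    sd = seg_means.std(axis=0, ddof=1) if n_segments > 1 else np.zeros(len(channels))
    scale = np.where(scale > 0, scale, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(scale > 0, (seg_means - med) / scale, 0.0)

    worst = np.abs(z).max(axis=1)  # per segment
    flagged = np.flatnonzero(worst > z_threshold)
    # cap removal, most aberrant first
    flagged = flagged[np.argsort(-worst[flagged])]
    budget = int(max_removed_fraction * n)
    removed: list[int] = []
    removed_events = 0
    for si in flagged:
        size = len(segments[si])
        if removed_events + size > budget:
            break
        removed.append(int(si))
        removed_events += size

    keep_mask = np.ones(n, dtype=bool)
    for si in removed:
        keep_mask[bounds[si]:bounds[si + 1]] = False
    kept = events.take(order[keep_mask])

    report = CleaningReport(
        segments_examined=n_segments,
        segments_removed=len(removed),
        events_removed=removed_events,
        removed_segments=sorted(removed),
        channel_max_abs_z={c: float(np.abs(z[:, j]).max()) for j, c in enumerate(channels)},
    )
    return kept, report


def subsample_events(events: EventTable, cap: int = 100_000, seed: int = 0) -> EventTable:
    """Uniform seeded subsample without replacement down to ``cap`` events.

    Tables at or under the cap are returned unchanged; otherwise exactly
    ``cap`` events are kept (original acquisition order preserved).
    """
    if cap <= 0:
        raise ValueError("cap must be > 0")
    if events.n_events <= cap:
        return events
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(events.n_events, size=cap, replace=False))
    return events.take(idx)
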