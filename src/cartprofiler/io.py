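"""Event-table container, FCS/CSV I/O, and hierarchical + boolean gating.

The :class:`EventTable` is the in-memory unit of cytometry data: an events x
channels matrix of fluorescence intensities with per-sample metadata and an
explicit scale state (``raw`` or ``arcsinh``) that every transform must
respect.  Gating is expressed as a tree of 1-D threshold or 2-D rectangle
predicates (root = all events, child populations are subsets of their
parent), and boolean signatures are conjunctions of per-marker positivity
terms evaluated inside a parent gate.

FCS support is a deliberately minimal single-dataset implementation of the
FCS 3.1 list-mode layout (float32/float64, little- or big-endian), enough to
round-trip the tables this package produces and to ingest plain unmixed
exports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EventTable",
    "RangeGate",
    "RectangleGate",
    "GateTree",
    "BooleanSignature",
    "DEFAULT_SIGNATURES",
    "read_events",
    "write_events_csv",
    "write_events_fcs",
    "apply_gates",
    "signature_frequency",
]


@dataclass
class EventTable:
    """Events x channels intensity matrix with sample metadata.

    ``values`` holds one row per event and one named column per channel
    (markers, plus optionally an acquisition ``Time`` channel).  ``truth``
    optionally carries synthetic ground-truth per-event annotation (population
    label, transgene positivity); it is aligned with ``values`` by position
    and is never exposed as a channel, so clustering and gating cannot see it.
    """

    values: pd.DataFrame
    sample_meta: dict = field(default_factory=dict)
    scale_state: str = "raw"
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate channel names: {dupes}")
        if self.scale_state not in ("raw", "arcsinh"):
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        if self.values.isna().any().any():
            raise ValueError("event table contains missing values")
        if self.truth is not None and len(self.truth) != len(self.values):
            raise ValueError("truth annotation must align with events")

    @property
    def channel_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_events(self) -> int:
        return len(self.values)

    def marker_channels(self, exclude: Sequence[str] = ()) -> list[str]:
        """Channel names minus the acquisition-time channel and ``exclude``."""
        drop = set(exclude) | {"Time"}
        return [c for c in self.values.columns if c not in drop]

    def take(self, index: np.ndarray) -> "EventTable":
        """Positional subset preserving metadata, scale state and truth."""
        truth = self.truth.iloc[index].reset_index(drop=True) if self.truth is not None else None
        return EventTable(
            values=self.values.iloc[index].reset_index(drop=True),
            sample_meta=dict(self.sample_meta),
            scale_state=self.scale_state,
            truth=truth,
        )

    def with_values(self, values: pd.DataFrame, scale_state: str | None = None) -> "EventTable":
        return EventTable(
            values=values,
            sample_meta=dict(self.sample_meta),
            scale_state=scale_state if scale_state is not None else self.scale_state,
            truth=self.truth,
        )


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RangeGate:
    """1-D threshold predicate: keep events with channel value above (or
    below) ``threshold``; ``side`` is ``"above"`` (>=) or ``"below"`` (<)."""

    channel: str
    threshold: float
    side: str = "above"

    def mask(self, values: pd.DataFrame) -> np.ndarray:
        if self.channel not in values.columns:
            raise KeyError(f"channel {self.channel!r} not in table")
        x = values[self.channel].to_numpy()
        if self.side == "above":
            return x >= self.threshold
        if self.side == "below":
            return x < self.threshold
        raise ValueError(f"side must be 'above' or 'below', got {self.side!r}")


@dataclass(frozen=True)
class RectangleGate:
    """2-D rectangle predicate on (x_channel, y_channel), inclusive bounds."""

    x_channel: str
    y_channel: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]

    def mask(self, values: pd.DataFrame) -> np.ndarray:
        x = values[self.x_channel].to_numpy()
        y = values[self.y_channel].to_numpy()
        return (
            (x >= self.x_range[0])
            & (x <= self.x_range[1])
            & (y >= self.y_range[0])
            & (y <= self.y_range[1])
        )


class GateTree:
    """Hierarchy of gates rooted at "all events".

    Nodes are added with a parent reference; the population at a node is the
    conjunction of every predicate on the path root -> node, so child
    populations are subsets of their parents by construction.
    """

    ROOT = "root"

    def __init__(self) -> None:
        self._gates: dict[str, RangeGate | RectangleGate] = {}
        self._parent: dict[str, str] = {}

    def add(self, name: str, gate: RangeGate | RectangleGate, parent: str = ROOT) -> "GateTree":
        if name == self.ROOT or name in self._gates:
            raise ValueError(f"gate name {name!r} already defined")
        if parent != self.ROOT and parent not in self._gates:
            raise KeyError(f"parent gate {parent!r} not defined")
        self._gates[name] = gate
        self._parent[name] = parent
        return self

    def path(self, node: str) -> list[str]:
        if node == self.ROOT:
            return []
        if node not in self._gates:
            raise KeyError(f"gate {node!r} not defined")
        chain: list[str] = []
        cur = node
        while cur != self.ROOT:
            chain.append(cur)
            cur = self._parent[cur]
        return chain[::-1]

    def mask(self, values: pd.DataFrame, node: str) -> np.ndarray:
        keep = np.ones(len(values), dtype=bool)
        for name in self.path(node):
            keep &= self._gates[name].mask(values)
        return keep

    @property
    def nodes(self) -> list[str]:
        return list(self._gates)

    @classmethod
    def from_config(cls, cfg: Sequence[Mapping]) -> "GateTree":
        """Build from a list of dicts (as parsed from the YAML gate config).

        Each entry: ``{name, parent, kind: range|rectangle, ...params}``.
        """
        tree = cls()
        for entry in cfg:
            kind = entry.get("kind", "range")
            if kind == "range":
                gate: RangeGate | RectangleGate = RangeGate(
                    channel=entry["channel"],
                    threshold=float(entry["threshold"]),
                    side=entry.get("side", "above"),
                )
            elif kind == "rectangle":
                gate = RectangleGate(
                    x_channel=entry["x_channel"],
                    y_channel=entry["y_channel"],
                    x_range=tuple(entry["x_range"]),
                    y_range=tuple(entry["y_range"]),
                )
            else:
                raise ValueError(f"unknown gate kind {kind!r}")
            tree.add(entry["name"], gate, parent=entry.get("parent", cls.ROOT))
        return tree


def apply_gates(events: EventTable, tree: GateTree, node: str) -> EventTable:
    """Subset ``events`` to the population at ``node`` of the gate tree.

    An empty result is a valid (empty) table, not an error.
    """
    keep = tree.mask(events.values, node)
    return events.take(np.flatnonzero(keep))


@dataclass(frozen=True)
class BooleanSignature:
    """Conjunction of per-marker positivity terms inside a parent gate.

    ``terms`` is a sequence of ``(marker, polarity)`` with polarity ``"+"``
    (at or above the positivity threshold) or ``"-"`` (below).  Positivity
    thresholds come from config or FMO-style controls and are supplied at
    evaluation time.
    """

    name: str
    terms: tuple[tuple[str, str], ...]
    parent: str = GateTree.ROOT

    def __post_init__(self) -> None:
        for marker, pol in self.terms:
            if pol not in ("+", "-"):
                raise ValueError(f"polarity for {marker!r} must be '+' or '-'")


# The four response-associated effector signatures used on single, viable
# CD3+ CD8+ cells: cytotoxicity, activation, tissue infiltration, resilience.
DEFAULT_SIGNATURES: tuple[BooleanSignature, ...] = (
    BooleanSignature("cytotoxicity", (("GrzB", "+"), ("CD26", "+"))),
    BooleanSignature("activation", (("BCL-2", "+"), ("CD26", "+"), ("CD154", "+"))),
    BooleanSignature("infiltration", (("CD103", "+"), ("TIGIT", "+"), ("CD26", "+"))),
    BooleanSignature("resilience", (("TIGIT", "+"),)),
)


def signature_frequency(
    events: EventTable,
    sig: BooleanSignature,
    thresholds: Mapping[str, float],
    tree: GateTree | None = None,
) -> float:
    """Percentage of parent-gate events satisfying every signature term.

    Returns ``nan`` (with a warning) when the parent population is empty.
    An empty conjunct list is vacuously true: 100%.
    """
    parent = events if tree is None or sig.parent == GateTree.ROOT else apply_gates(events, tree, sig.parent)
    n_parent = parent.n_events
    if n_parent == 0:
        warnings.warn(f"empty parent population for signature {sig.name!r}", stacklevel=2)
        return float("nan")
    keep = np.ones(n_parent, dtype=bool)
    for marker, pol in sig.terms:
        if marker not in parent.values.columns:
            raise KeyError(f"signature marker {marker!r} not in panel")
        if marker not in thresholds:
            raise KeyError(f"no positivity threshold configured for {marker!r}")
        x = parent.values[marker].to_numpy()
        pos = x >= thresholds[marker]
        keep &= pos if pol == "+" else ~pos
    return 100.0 * keep.sum() / n_parent


# ---------------------------------------------------------------------------
# CSV dialect: events x channels with header row; sample_meta in sidecar YAML
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_events_csv(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    events.values.to_csv(path, index=False)
    meta = dict(events.sample_meta)
    meta["scale_state"] = events.scale_state
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def _read_events_csv(path: Path) -> EventTable:
    values = pd.read_csv(path)
    meta: dict = {}
    scale_state = "raw"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        scale_state = meta.pop("scale_state", "raw")
    return EventTable(values=values, sample_meta=meta, scale_state=scale_state)


# ---------------------------------------------------------------------------
# Minimal FCS 3.1 list-mode writer / reader
# ---------------------------------------------------------------------------

_FCS_DELIM = "/"


def _fcs_text(keys: dict[str, str]) -> bytes:
    parts = [""]
    for k, v in keys.items():
        parts.append(k)
        parts.append(str(v))
    return (_FCS_DELIM.join(parts) + _FCS_DELIM).encode("ascii")


def write_events_fcs(events: EventTable, path: str | Path) -> Path:
    """Write an FCS 3.1 file: single dataset, float32 list mode."""
    path = Path(path)
    data = events.values.to_numpy(dtype="<f4")
    n_events, n_par = data.shape
    keys: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(events.channel_names, start=1):
        keys[f"$P{i}N"] = name
        keys[f"$P{i}B"] = "32"
        keys[f"$P{i}E"] = "0,0"
        rng = float(np.abs(data[:, i - 1]).max()) if n_events else 1.0
        keys[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)

    header_len = 58
    # two passes: offsets appear inside TEXT, so sizes must stabilize
    data_len = data.nbytes
    begin_data = 0
    for _ in range(3):
        keys["$BEGINDATA"] = str(begin_data)
        keys["$ENDDATA"] = str(begin_data + data_len - 1 if data_len else 0)
        text = _fcs_text(keys)
        new_begin = header_len + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    keys["$BEGINDATA"] = str(begin_data)
    keys["$ENDDATA"] = str(begin_data + data_len - 1 if data_len else 0)
    text = _fcs_text(keys)

    text_begin = header_len
    text_end = header_len + len(text) - 1
    data_end = begin_data + data_len - 1 if data_len else 0

    def _off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _off(text_begin) + _off(text_end) + _off(begin_data if data_len else 0) + _off(data_end) + _off(0) + _off(0)
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
    return path


def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    fields = raw.decode("latin-1").split(delim)[1:]
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        fields = fields[:-1]
    return {fields[i]: fields[i + 1] for i in range(0, len(fields), 2)}


def _read_events_fcs(path: Path) -> EventTable:
    with open(path, "rb") as fh:
        header = fh.read(58)
        if not header[:6].startswith(b"FCS3") and not header[:6].startswith(b"FCS2"):
            raise IOError(f"{path} is not an FCS file")
        text_begin = int(header[10:18])
        text_end = int(header[18:26])
        fh.seek(text_begin)
        text = _parse_fcs_text(fh.read(text_end - text_begin + 1))

        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        begin_data = int(text.get("$BEGINDATA") or header[26:34])
        dtype_code = text.get("$DATATYPE", "F").strip().upper()
        byteord = text.get("$BYTEORD", "1,2,3,4").strip()
        endian = "<" if byteord.startswith("1") else ">"
        if dtype_code == "F":
            dt = np.dtype(endian + "f4")
        elif dtype_code == "D":
            dt = np.dtype(endian + "f8")
        else:
            raise IOError(f"unsupported FCS $DATATYPE {dtype_code!r} (only F/D)")
        fh.seek(begin_data)
        buf = fh.read(n_tot * n_par * dt.itemsize)
    data = np.frombuffer(buf, dtype=dt).reshape(n_tot, n_par).astype(float)
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    values = pd.DataFrame(data, columns=names)
    return EventTable(values=values, sample_meta={}, scale_state="raw")


def read_events(
    path: str | Path,
    dialect: str = "csv",
    panel: Sequence[str] | None = None,
) -> EventTable:
    """Read an event table from ``path`` (``dialect`` = ``csv`` or ``fcs``).

    If a ``panel`` of expected channel names is given, unknown channels
    trigger a warning but are passed through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if dialect == "csv":
        table = _read_events_csv(path)
    elif dialect == "fcs":
        table = _read_events_fcs(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if panel is not None:
        unknown = [c for c in table.channel_names if c not in set(panel) | {"Time"}]
        if unknown:
            warnings.warn(f"channels not in configured panel: {unknown}", stacklevel=2)
    return table
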