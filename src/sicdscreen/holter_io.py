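"""ASCII Holter recording I/O and the 10-second segment grid.

The on-disk dialect is a minimal self-describing sample table::

    # fs=500
    # channels=primary,alternate,secondary
    # subject=P001
    # subgroup=HCM
    0.012 -0.004 0.031
    ...

One row per time point, one whitespace-separated column per channel,
values in millivolts.  Channel roles name the three S-ICD sensing
vectors the Holter leads surrogate; a recording may omit roles (e.g. a
missing secondary lead), and downstream analyses then evaluate the
vectors that are present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical channel order: the three programmable S-ICD sensing vectors.
CHANNEL_ROLES = ("primary", "alternate", "secondary")

#: Default analysis window: one screening-strip-sized chunk of ECG.
DEFAULT_WINDOW_S = 10.0


@dataclass
class ECGRecording:
    """Multi-channel uniformly sampled ECG in millivolts.

    ``channels`` maps role -> 1-D float array; all present channels must
    have equal length.  Roles not in the mapping are "missing" and are
    skipped (never imputed) by downstream code.
    """

    sampling_rate: float
    channels: dict[str, np.ndarray]
    subject_id: str = ""
    subgroup: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            raise ValueError("recording must have at least one channel")
        lengths = set()
        for role, x in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            arr = np.asarray(x, dtype=float)
            self.channels[role] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(r for r in CHANNEL_ROLES if r in self.channels)

    def missing_roles(self) -> tuple[str, ...]:
        return tuple(r for r in CHANNEL_ROLES if r not in self.channels)


@dataclass
class Segment:
    """One analysis window of one channel.

    ``segment_index`` is 0-based; segment *k* covers the half-open time
    interval [k*w, (k+1)*w) seconds with w the window length (10 s by
    default, i.e. 5000 samples at 500 Hz).
    """

    channel_role: str
    segment_index: int
    samples: np.ndarray
    sampling_rate: float
    window_s: float = DEFAULT_WINDOW_S

    @property
    def start_time(self) -> float:
        return self.segment_index * self.window_s

    def __len__(self) -> int:
        return self.samples.shape[0]


def write_ascii(recording: ECGRecording, path) -> None:
    """Write a recording in the ASCII sample-table dialect.

    Values are written with 6 significant digits, enough for a lossless
    round trip at physiological millivolt amplitudes.
    """
    roles = recording.roles
    data = np.column_stack([recording.channels[r] for r in roles])
    header = (
        f"fs={recording.sampling_rate:g}\n"
        f"channels={','.join(roles)}\n"
        f"subject={recording.subject_id}\n"
        f"subgroup={recording.subgroup}"
    )
    np.savetxt(path, data, fmt="%.6g", header=header, comments="# ")


def read_ascii(path) -> ECGRecording:
    """Read a recording from the ASCII sample-table dialect.

    Raises ``ValueError`` (naming the offending line) on ragged rows,
    unknown channel roles, or an empty file.  Parsing is
    locale-independent: the decimal separator is always a dot.
    """
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ValueError(
                    f"{path}: ragged row at line {lineno}: expected {ncols} "
                    f"columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: bad numeric value at line {lineno}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    if "fs" not in meta or "channels" not in meta:
        raise ValueError(f"{path}: missing required header fields fs/channels")
    roles = tuple(r.strip() for r in meta["channels"].split(","))
    for role in roles:
        if role not in CHANNEL_ROLES:
            raise ValueError(f"{path}: unknown channel role {role!r}")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] != len(roles):
        raise ValueError(
            f"{path}: header declares {len(roles)} channels but rows have "
            f"{data.shape[1]} columns"
        )
    channels = {role: data[:, j].copy() for j, role in enumerate(roles)}
    return ECGRecording(
        sampling_rate=float(meta["fs"]),
        channels=channels,
        subject_id=meta.get("subject", ""),
        subgroup=meta.get("subgroup", ""),
    )


def segment_recording(
    recording: ECGRecording, window_s: float = DEFAULT_WINDOW_S
) -> dict[str, list[Segment]]:
    """Cut each channel into consecutive non-overlapping windows.

    Returns ``{role: [Segment, ...]}`` with ``floor(duration / window_s)``
    segments per channel; a trailing partial window is dropped so that
    every segment has exactly ``window_s * sampling_rate`` samples.
    Segments hold views into the recording arrays (no copy).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_win = int(round(window_s * recording.sampling_rate))
    n_segments = recording.n_samples // n_win
    if n_segments == 0:
        logger.warning(
            "window (%.3g s) longer than recording (%.3g s); no segments",
            window_s,
            recording.duration_s,
        )
    out: dict[str, list[Segment]] = {}
    for role in recording.roles:
        x = recording.channels[role]
        out[role] = [
            Segment(
                channel_role=role,
                segment_index=k,
                samples=x[k * n_win : (k + 1) * n_win],
                sampling_rate=recording.sampling_rate,
                window_s=window_s,
            )
            for k in range(n_segments)
        ]
    return out
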