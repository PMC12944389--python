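"""Core signal container and plain-text I/O shared by every pipeline stage.

A :class:`Signal` is a uniformly sampled single-channel amplitude series
(typically surface EMG in mV) together with its sampling rate and an
optional *resting span*: a half-open ``[start, end)`` sample-index interval
during which the muscle is known to be relaxed.  The resting span is what
the rest-calibrated threshold estimator is built on.

Samples are stored as one-column CSV; the sampling rate and resting span
live in a JSON sidecar with the same stem (``signal.csv`` + ``signal.json``)
so the sample file stays trivially interoperable with other tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Signal", "read_signal", "write_signal"]


@dataclass(frozen=True)
class Signal:
    """Uniformly sampled amplitude series.

    Parameters
    ----------
    samples : ndarray
        Finite amplitude values, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    rest_span : tuple of (int, int), optional
        Half-open ``[start, end)`` sample-index interval marking the
        resting (relaxed) segment, or ``None`` when unknown.
    """

    samples: np.ndarray
    fs: float
    rest_span: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("signal needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")
        if self.rest_span is not None:
            start, end = int(self.rest_span[0]), int(self.rest_span[1])
            if not (0 <= start < end <= samples.size):
                raise ValueError(
                    f"rest_span [{start}, {end}) must lie inside [0, {samples.size})"
                )
            object.__setattr__(self, "rest_span", (start, end))

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self) / self.fs

    @property
    def rest_samples(self) -> np.ndarray:
        """Samples inside the resting span; raises if no span is set."""
        if self.rest_span is None:
            raise ValueError("signal has no rest_span")
        start, end = self.rest_span
        return self.samples[start:end]

    def with_samples(self, samples: np.ndarray) -> "Signal":
        """Copy of this signal with replaced samples (fs/rest_span kept)."""
        return Signal(np.asarray(samples, dtype=float), self.fs, self.rest_span)

    def time_axis(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self)) / self.fs


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_signal(
    path: str | Path,
    fs: float | None = None,
    rest_seconds: float | None = None,
) -> Signal:
    """Read a one-column CSV of amplitudes into a :class:`Signal`.

    An optional single header line is skipped automatically.  If a JSON
    sidecar (same stem, ``.json``) exists, its ``fs`` and ``rest_span``
    are used as defaults; explicit arguments override them.

    Parameters
    ----------
    path : path
        CSV file with one numeric column.
    fs : float, optional
        Sampling rate in Hz.  Required when no sidecar is present.
    rest_seconds : float, optional
        Duration of the resting prefix; stored as
        ``rest_span = [0, round(rest_seconds * fs))``.

    Raises
    ------
    ValueError
        On non-numeric rows (including NaN) or a rest span that does not
        fit inside the record.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise ValueError("sampling rate not given and no sidecar found")

    frame = pd.read_csv(path, header=None, comment="#")
    if frame.shape[1] != 1:
        raise ValueError(f"expected one column, found {frame.shape[1]}")
    col = frame.iloc[:, 0]
    # A first row that cannot be parsed as a float at all is a header; a row
    # that parses to NaN/inf is data and fails the finiteness check below.
    values = pd.to_numeric(col, errors="coerce")
    if isinstance(col.iloc[0], str):
        try:
            float(col.iloc[0])
        except ValueError:
            values = values.iloc[1:]
    arr = values.to_numpy(dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"non-numeric or non-finite sample at row {bad}")

    rest_span: tuple[int, int] | None = None
    if rest_seconds is not None:
        n_rest = int(round(rest_seconds * fs))
        if n_rest >= arr.size:
            raise ValueError(
                f"rest_seconds covers {n_rest} samples but record has only {arr.size}"
            )
        if n_rest > 0:
            rest_span = (0, n_rest)
    elif meta.get("rest_span") is not None:
        start, end = meta["rest_span"]
        rest_span = (int(start), int(end))

    return Signal(arr, float(fs), rest_span)


def write_signal(signal: Signal, path: str | Path) -> None:
    """Write samples as one-column CSV plus a JSON sidecar with fs/rest_span.

    Round-trips through :func:`read_signal` losslessly (<= 1e-9 relative
    error) because samples are written at full float precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.Series(signal.samples).to_csv(path, index=False, header=False, float_format="%.17g")
    meta = {
        "fs": signal.fs,
        "rest_span": list(signal.rest_span) if signal.rest_span is not None else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta))
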