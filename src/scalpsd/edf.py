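"""Recording container and EDF (European Data Format) I/O.

DC-coupled voltage series are stored as a :class:`Recording`: a channel x
sample array in microvolts plus sampling rate, start time and an optional
:class:`~scalpsd.layouts.ElectrodeLayout`.  Files are written as plain
continuous EDF — the 256-byte-header, 16-bit-integer container that EDF+
extends — which every EDF+ reader accepts.  Voltages are quantised onto
the physical range (default ±3200 µV, wide enough for ECoG DC-shifts
around −3.8 mV), so a write/read round trip is exact to within
``(phys_max − phys_min) / 2**16`` ≈ 0.1 µV at the default range.

Missing samples are carried as a per-channel boolean mask on the
in-memory object; EDF has no missing-data notion, so masks are not
persisted (masked samples are written as their stored voltage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .layouts import ElectrodeLayout

DEFAULT_PHYS_RANGE_UV = 3200.0
# symmetric digital range so 0 µV encodes exactly
_DIGITAL_MIN, _DIGITAL_MAX = -32767, 32767


class EDFFormatError(ValueError):
    """Raised when a file is not readable EDF."""


class LayoutMismatchError(ValueError):
    """Raised when no file channel matches the requested layout."""


@dataclass
class Recording:
    """Multichannel DC voltage time series in microvolts."""

    labels: list[str]
    data: np.ndarray  # (n_channels, n_samples) µV
    rate: float  # Hz
    start_time: datetime = field(
        default_factory=lambda: datetime(2000, 1, 1, 0, 0, 0)
    )
    layout: ElectrodeLayout | None = None
    mask: np.ndarray | None = None  # True where the sample is missing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_channels, n_samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data")
        unmasked = self.data if self.mask is None else self.data[~self.mask]
        if unmasked.size and not np.all(np.isfinite(unmasked)):
            raise ValueError("non-finite voltages must be masked")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from the start of the recording."""
        return np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def live_labels(self) -> list[str]:
        if self.layout is None:
            return list(self.labels)
        dead = self.layout.dead_labels
        return [lab for lab in self.labels if lab not in dead]


def _record_geometry(rate: float, n_samples: int) -> tuple[float, int]:
    """Choose an EDF data-record duration holding a whole number of samples."""
    if rate >= 1 and abs(rate - round(rate)) < 1e-9:
        return 1.0, int(round(rate))
    # slow (sub-hertz) signals: one sample per record
    period = 1.0 / rate
    if abs(period - round(period)) > 1e-6:
        raise ValueError(f"cannot map rate {rate} Hz onto EDF records")
    return float(round(period)), 1


def write_recording(
    rec: Recording,
    path,
    phys_range_uv: float = DEFAULT_PHYS_RANGE_UV,
) -> None:
    """Write a Recording to a continuous EDF file with physical unit uV.

    Raises
    ------
    ValueError
        If any voltage falls outside ``±phys_range_uv`` (scaling error),
        or the sampling rate cannot be expressed in EDF data records.
    """
    phys_min, phys_max = -phys_range_uv, phys_range_uv
    finite = rec.data[np.isfinite(rec.data)]
    if finite.size and (finite.min() < phys_min or finite.max() > phys_max):
        raise ValueError(
            f"voltages exceed physical range ±{phys_range_uv} µV; "
            "increase phys_range_uv"
        )
    record_dur, spr = _record_geometry(rec.rate, rec.n_samples)
    n_records = math.ceil(rec.n_samples / spr) if rec.n_samples else 0
    ns = rec.n_channels

    gain = (phys_max - phys_min) / (_DIGITAL_MAX - _DIGITAL_MIN)
    data = np.nan_to_num(rec.data, nan=0.0)
    digital = np.round((data - phys_min) / gain + _DIGITAL_MIN)
    digital = np.clip(digital, _DIGITAL_MIN, _DIGITAL_MAX).astype("<i2")
    # pad the trailing partial record with the digital value of 0 µV
    pad = n_records * spr - rec.n_samples
    if pad:
        zero = np.round((0.0 - phys_min) / gain + _DIGITAL_MIN).astype("<i2")
        digital = np.concatenate(
            [digital, np.full((ns, pad), zero, dtype="<i2")], axis=1
        )

    t = rec.start_time
    hdr = b"".join(
        [
            b"0".ljust(8),
            b"X X X X".ljust(80),  # patient id
            b"Startdate X X X X".ljust(80),  # recording id
            t.strftime("%d.%m.%y").encode().ljust(8),
            t.strftime("%H.%M.%S").encode().ljust(8),
            str(256 * (1 + ns)).encode().ljust(8),
            b"".ljust(44),  # reserved; blank = plain EDF
            str(n_records).encode().ljust(8),
            _fmt_number(record_dur).ljust(8),
            str(ns).encode().ljust(4),
        ]
    )

    def col(values, width):
        return b"".join(str(v).encode()[:width].ljust(width) for v in values)

    hdr += col(rec.labels, 16)
    hdr += col([""] * ns, 80)  # transducer
    hdr += col(["uV"] * ns, 8)
    hdr += col([_fmt_number(phys_min).decode()] * ns, 8)
    hdr += col([_fmt_number(phys_max).decode()] * ns, 8)
    hdr += col([_DIGITAL_MIN] * ns, 8)
    hdr += col([_DIGITAL_MAX] * ns, 8)
    hdr += col([""] * ns, 80)  # prefiltering
    hdr += col([spr] * ns, 8)
    hdr += col([""] * ns, 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def _fmt_number(x: float) -> bytes:
    if x == int(x):
        return str(int(x)).encode()
    return f"{x:.8g}".encode()[:8]


def read_recording(
    path, layout: ElectrodeLayout | None = None
) -> Recording:
    """Read an EDF/EDF+ file, keeping channels that match ``layout``.

    Channel matching against the layout is case-insensitive; unmatched
    channels are dropped (their labels are recorded in the returned
    object's ``dropped`` attribute).  With ``layout=None`` all channels
    are kept.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFFormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode().strip())
            record_dur = float(head[244:252].decode().strip())
            ns = int(head[252:256].decode().strip())
            day, month, year = map(int, head[168:176].decode().strip().split("."))
            hh, mm, ss = map(int, head[176:184].decode().strip().split("."))
        except (ValueError, UnicodeDecodeError) as exc:
            raise EDFFormatError(f"{path}: malformed EDF header") from exc
        year += 2000 if year < 85 else 1900
        start = datetime(year, month, day, hh, mm, ss)

        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise EDFFormatError(f"{path}: truncated signal header")

        def fields(offset, width, conv=str):
            out = []
            for i in range(ns):
                raw = sig[offset * ns + i * width : offset * ns + (i + 1) * width]
                out.append(conv(raw.decode("ascii", "replace").strip()))
            return out

        labels = fields(0, 16)
        phys_min = fields(16 + 80 + 8, 8, float)
        phys_max = fields(16 + 80 + 8 + 8, 8, float)
        dig_min = fields(16 + 80 + 8 + 16, 8, int)
        dig_max = fields(16 + 80 + 8 + 24, 8, int)
        spr = fields(16 + 80 + 8 + 32 + 80, 8, int)

        payload = np.frombuffer(fh.read(), dtype="<i2")

    rec_len = sum(spr)
    if n_records < 0:  # unknown length: infer from payload
        n_records = payload.size // rec_len
    payload = payload[: n_records * rec_len].reshape(n_records, rec_len)

    keep = list(range(ns))
    dropped: list[str] = []
    canonical = dict(enumerate(labels))
    if layout is not None:
        lut = {lab.lower(): lab for lab in layout.labels}
        keep, canonical = [], {}
        for i, lab in enumerate(labels):
            if lab.lower() in lut:
                keep.append(i)
                canonical[i] = lut[lab.lower()]
            else:
                dropped.append(lab)
        if not keep:
            raise LayoutMismatchError(
                f"{path}: no channel matches layout {layout.name!r}"
            )

    rates = {spr[i] / record_dur for i in keep}
    if len(rates) != 1:
        raise EDFFormatError(f"{path}: mixed sampling rates among kept channels")
    rate = rates.pop()

    offsets = np.concatenate([[0], np.cumsum(spr)])
    channels = []
    for i in keep:
        dig = payload[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        channels.append((dig - dig_min[i]) * gain + phys_min[i])
    rec = Recording(
        labels=[canonical[i] for i in keep],
        data=np.array(channels) if channels else np.empty((0, 0)),
        rate=rate,
        start_time=start,
        layout=layout,
    )
    rec.dropped = dropped  # type: ignore[attr-defined]
    return rec


def quantization_step(phys_range_uv: float = DEFAULT_PHYS_RANGE_UV) -> float:
    """Voltage resolution of the 16-bit EDF encoding, in µV."""
    return 2 * phys_range_uv / (_DIGITAL_MAX - _DIGITAL_MIN)
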