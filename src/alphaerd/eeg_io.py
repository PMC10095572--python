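"""Reading and writing EEG recordings and subject metadata.

Two on-disk formats are supported:

* **EDF** (European Data Format, 16-bit): for interoperability with standard
  EEG software.  The implementation here is a minimal, self-contained reader
  and writer for continuous EDF with one data record per second, which is all
  the pipeline needs; it is not a general EDF+ library.
* **fixture**: a NumPy ``.npz`` array container with a JSON sidecar carrying
  channel labels, sampling rate and condition — bit-exact round-trips for fast
  tests.

Channel labels are normalized to canonical upper-case 10-20 names on read
("Fp1", "fp1" and "EEG FP1" all become "FP1").  Signals are in µV throughout;
the EDF writer declares the physical dimension as ``uV`` and the reader
asserts it.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS_16, FRONTAL_CHANNELS, REFERENCE, normalize_label

__all__ = [
    "EEGRecording",
    "Montage",
    "ChannelError",
    "FormatError",
    "MetadataError",
    "read_recording",
    "write_recording",
    "select_frontal",
    "load_metadata",
    "genotype_group",
    "write_metadata",
]


class ChannelError(ValueError):
    """A required channel is absent from a recording."""


class FormatError(ValueError):
    """A file could not be parsed in the declared format."""


class MetadataError(ValueError):
    """The subject metadata table violates its contract."""


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus the reference description (metadata only)."""

    channel_labels: tuple[str, ...] = CHANNELS_16
    reference: str = REFERENCE

    def __post_init__(self) -> None:
        missing = [c for c in FRONTAL_CHANNELS if c not in self.channel_labels]
        if missing:
            raise ChannelError(f"montage lacks analysis channels: {', '.join(missing)}")


@dataclass
class EEGRecording:
    """Multichannel EEG signal in µV with montage labels and a condition tag."""

    subject_id: str
    condition: str  # "rest" or "task"
    channel_labels: tuple[str, ...]
    sampling_rate: float
    samples: np.ndarray  # (n_channels, n_samples), µV

    def __post_init__(self) -> None:
        self.channel_labels = tuple(normalize_label(c) for c in self.channel_labels)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples must be (n_channels, n_samples)")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain NaN")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        label = normalize_label(label)
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ChannelError(f"channel {label} not present") from None
        return self.samples[idx]


def select_frontal(recording: EEGRecording) -> EEGRecording:
    """Restrict a recording to the frontal analysis channels (F3, F4, FP1, FP2)."""
    missing = [c for c in FRONTAL_CHANNELS if c not in recording.channel_labels]
    if missing:
        raise ChannelError(
            f"recording {recording.subject_id}/{recording.condition} missing "
            f"channel(s): {', '.join(missing)}"
        )
    idx = [recording.channel_labels.index(c) for c in FRONTAL_CHANNELS]
    return replace(
        recording,
        channel_labels=FRONTAL_CHANNELS,
        samples=recording.samples[idx].copy(),
    )


# ---------------------------------------------------------------------------
# fixture format: .npz + .json sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_fixture(recording: EEGRecording, path: Path) -> None:
    np.savez_compressed(path, samples=recording.samples)
    meta = {
        "subject_id": recording.subject_id,
        "condition": recording.condition,
        "channel_labels": list(recording.channel_labels),
        "sampling_rate": recording.sampling_rate,
        "units": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_fixture(path: Path) -> EEGRecording:
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"fixture sidecar {side} not found")
    try:
        meta = json.loads(side.read_text())
        with np.load(path) as npz:
            samples = npz["samples"]
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise FormatError(f"cannot parse fixture {path}: {exc}") from exc
    if meta.get("units", "uV") != "uV":
        raise FormatError(f"fixture {path}: unsupported units {meta['units']!r}")
    return EEGRecording(
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        channel_labels=tuple(meta["channel_labels"]),
        sampling_rate=float(meta["sampling_rate"]),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# minimal EDF (16-bit, one data record per second)
# ---------------------------------------------------------------------------

_EDF_UV_DIMENSIONS = {"uV", "µV", "uv"}


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {value!r}")
    return b.ljust(width)


def _phys_str(value: float, width: int = 8) -> str:
    """Shortest decimal form of a physical bound that fits the 8-char field."""
    for digits in range(6, 0, -1):
        s = f"{value:.{digits}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot encode physical bound {value!r} in {width} chars")


def _write_edf(recording: EEGRecording, path: Path) -> None:
    fs = recording.sampling_rate
    spr = int(round(fs))  # samples per 1-s data record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = len(recording.channel_labels)
    n_rec = recording.samples.shape[1] // spr
    if n_rec * spr != recording.samples.shape[1]:
        raise ValueError("EDF writer requires a whole number of 1-s records")

    phys_min = np.empty(n_ch)
    phys_max = np.empty(n_ch)
    digital = np.empty((n_ch, n_rec * spr), dtype="<i2")
    dig_min, dig_max = -32768, 32767
    for ci in range(n_ch):
        x = recording.samples[ci]
        span = max(float(np.max(np.abs(x))), 1e-6) * 1.0001
        # the header stores at most 8 ASCII chars; scale with the value as
        # written, not the full-precision one, or the round trip drifts
        span = float(_phys_str(span))
        while span < np.max(np.abs(x)):
            span = float(_phys_str(span * 1.001))
        phys_min[ci], phys_max[ci] = -span, span
        scale = (dig_max - dig_min) / (2 * span)
        digital[ci] = np.clip(
            np.round((x - phys_min[ci]) * scale) + dig_min, dig_min, dig_max
        ).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(f"subject {recording.subject_id}"[:80], 80))
        fh.write(_edf_field(f"condition {recording.condition}"[:80], 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(header_bytes), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_rec), 8))
        fh.write(_edf_field("1", 8))  # record duration, seconds
        fh.write(_edf_field(str(n_ch), 4))
        for lab in recording.channel_labels:
            fh.write(_edf_field(f"EEG {lab}"[:16], 16))
        for _ in range(n_ch):
            fh.write(_edf_field("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))
        for ci in range(n_ch):
            fh.write(_edf_field(_phys_str(phys_min[ci]), 8))
        for ci in range(n_ch):
            fh.write(_edf_field(_phys_str(phys_max[ci]), 8))
        for _ in range(n_ch):
            fh.write(_edf_field(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_edf_field(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_edf_field(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 32))  # reserved
        # data records: per record, all samples of signal 0, then signal 1, ...
        per_record = digital.reshape(n_ch, n_rec, spr)
        for ri in range(n_rec):
            fh.write(per_record[:, ri, :].tobytes())


def _read_edf(path: Path, condition: str | None = None) -> EEGRecording:
    try:
        with open(path, "rb") as fh:
            head = fh.read(256)
            if len(head) < 256:
                raise FormatError(f"{path}: truncated EDF header")
            patient = head[8:88].decode("ascii", "replace").strip()
            rec_field = head[88:168].decode("ascii", "replace").strip()
            n_rec = int(head[236:244])
            rec_dur = float(head[244:252])
            n_ch = int(head[252:256])
            sig = fh.read(256 * n_ch)

            def sfield(offset: int, width: int) -> list[str]:
                base = offset * n_ch
                return [
                    sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                    for i in range(n_ch)
                ]

            labels = sfield(0, 16)
            dims = sfield(16 + 80, 8)
            pmin = [float(v) for v in sfield(16 + 80 + 8, 8)]
            pmax = [float(v) for v in sfield(16 + 80 + 16, 8)]
            dmin = [int(v) for v in sfield(16 + 80 + 24, 8)]
            dmax = [int(v) for v in sfield(16 + 80 + 32, 8)]
            spr = [int(v) for v in sfield(16 + 80 + 40 + 80, 8)]
            raw = np.frombuffer(fh.read(), dtype="<i2")
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse EDF {path}: {exc}") from exc

    for d in dims:
        if d not in _EDF_UV_DIMENSIONS:
            raise FormatError(f"{path}: physical dimension {d!r} is not µV")
    rec_len = sum(spr)
    if raw.size < n_rec * rec_len:
        raise FormatError(f"{path}: data section shorter than declared")
    raw = raw[: n_rec * rec_len].reshape(n_rec, rec_len)
    samples = np.empty((n_ch, n_rec * spr[0]))
    offset = 0
    for ci in range(n_ch):
        block = raw[:, offset : offset + spr[ci]].astype(np.float64)
        scale = (pmax[ci] - pmin[ci]) / (dmax[ci] - dmin[ci])
        samples[ci] = ((block - dmin[ci]) * scale + pmin[ci]).ravel()
        offset += spr[ci]

    subject_id = patient.removeprefix("subject ").strip() or path.stem
    if condition is None:
        condition = rec_field.removeprefix("condition ").strip() or "unknown"
    return EEGRecording(
        subject_id=subject_id,
        condition=condition,
        channel_labels=tuple(labels),
        sampling_rate=spr[0] / rec_dur,
        samples=samples,
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    condition: str | None = None,
    require_channels: tuple[str, ...] | None = None,
) -> EEGRecording:
    """Read a recording from EDF or from the fixture format.

    Format is inferred from the extension when not given.  ``require_channels``
    (default: the frontal analysis set when the montage is incomplete is an
    error) lists channels that must be present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "fixture"
    if format == "edf":
        rec = _read_edf(path, condition)
    elif format == "fixture":
        rec = _read_fixture(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if rec.sampling_rate <= 0:
        raise FormatError(f"{path}: non-positive sampling rate")
    if require_channels:
        missing = [c for c in require_channels if normalize_label(c) not in rec.channel_labels]
        if missing:
            raise ChannelError(f"{path}: missing channel(s): {', '.join(missing)}")
    return rec


def write_recording(recording: EEGRecording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as EDF (``.edf``) or as the fixture format (anything else)."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "fixture"
    if format == "edf":
        _write_edf(recording, path)
    elif format == "fixture":
        _write_fixture(recording, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# subject metadata
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("subject_id", "clu_genotype", "apoe_group", "age", "sex")
_VALID_GENOTYPES = {"CC", "CT", "TT"}


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Load and validate the subject metadata CSV.

    Requires unique subject_id, genotypes in {CC, CT, TT} and no missing values
    in the covariates the group model uses.
    """
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise MetadataError(f"cannot read metadata {path}: {exc}") from exc
    if table.empty:
        raise MetadataError(f"metadata {path} is empty")
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise MetadataError(f"metadata missing column(s): {', '.join(missing_cols)}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if not dup.empty:
        raise MetadataError(f"duplicate subject_id: {', '.join(map(str, dup.unique()))}")
    bad = ~table["clu_genotype"].isin(_VALID_GENOTYPES)
    if bad.any():
        rows = ", ".join(str(i) for i in table.index[bad])
        raise MetadataError(f"unknown clu_genotype at row(s) {rows}")
    na = table[list(_REQUIRED_COLUMNS)].isna()
    if na.any().any():
        rows = ", ".join(str(i) for i in table.index[na.any(axis=1)])
        raise MetadataError(f"missing covariate values at row(s) {rows}")
    return table


def genotype_group(table: pd.DataFrame) -> pd.DataFrame:
    """Add the pooled ``clu_group`` column: CC stays CC; CT and TT pool to CT&TT."""
    out = table.copy()
    out["clu_group"] = np.where(out["clu_genotype"] == "CC", "CC", "CT&TT")
    return out


def write_metadata(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path
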