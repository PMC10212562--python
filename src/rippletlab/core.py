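"""Domain containers and sweep-table I/O shared by every analysis module.

The universal input object is a :class:`SweepSet`: a list of stimulus-aligned
sampled traces (LFP, current clamp, or voltage clamp) recorded at a common
rate, together with the optogenetic stimulus protocol and the pharmacological
condition. Sweeps are serialized as a plain-text "sweep table" CSV: ``# key=value``
header lines followed by a ``time_ms,sweep_000,...`` column table.

Conventions used throughout the package:

* all times are milliseconds, double precision; sample 0 is sweep start;
* reported event latencies are measured from light onset
  (``protocol.onset`` subtracted);
* voltages in mV, currents in pA; sampling defaults to 20 kHz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CONDITIONS",
    "TRACE_KINDS",
    "FormatError",
    "ValidationError",
    "StimulusProtocol",
    "Trace",
    "SweepSet",
    "read_sweepset",
    "write_sweepset",
    "average_sweeps",
    "get_logger",
]

TRACE_KINDS = ("lfp", "current_clamp", "voltage_clamp")
CONDITIONS = ("control", "cnqx_apv", "ttx", "gabazine")

DEFAULT_RATE_HZ = 20_000.0
DEFAULT_SWEEP_MS = 50.0


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class FormatError(ValueError):
    """A sweep-table file is malformed; the message names the offending line."""


def get_logger(name: str = "rippletlab") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s [%(levelname)s] %(name)s: %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass(frozen=True)
class StimulusProtocol:
    """Optogenetic light-pulse protocol.

    Parameters
    ----------
    onset : float
        Light onset, ms from sweep start.
    duration : float
        Pulse duration, ms (1-10 typical).
    intensity : float
        Fraction of maximal light intensity, in (0, 1].
    inter_trial_interval : float
        Seconds between consecutive sweeps.
    """

    onset: float = 1.0
    duration: float = 2.0
    intensity: float = 0.9
    inter_trial_interval: float = 8.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("stimulus duration must be > 0")
        if not 0 < self.intensity <= 1:
            raise ValidationError("stimulus intensity must be in (0, 1]")
        if self.onset < 0:
            raise ValidationError("stimulus onset must be >= 0")


@dataclass
class Trace:
    """A single uniformly sampled sweep."""

    samples: np.ndarray
    rate: float = DEFAULT_RATE_HZ
    kind: str = "lfp"
    holding: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("trace samples must be a 1-D vector")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be > 0")
        if self.kind not in TRACE_KINDS:
            raise ValidationError(f"unknown trace kind {self.kind!r}")
        if (self.holding is not None) != (self.kind == "voltage_clamp"):
            raise ValidationError(
                "holding potential must be present iff kind is voltage_clamp"
            )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return len(self.samples) * self.dt_ms


@dataclass
class SweepSet:
    """Repeated stimulus-aligned sweeps plus protocol and condition metadata."""

    sweeps: list[Trace]
    protocol: StimulusProtocol
    condition: str = "control"
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValidationError("a SweepSet needs at least one sweep")
        first = self.sweeps[0]
        for i, sw in enumerate(self.sweeps):
            if len(sw) != len(first) or sw.rate != first.rate or sw.kind != first.kind:
                raise ValidationError(
                    f"sweep {i} differs from sweep 0 in length, rate or kind"
                )
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.protocol.onset + self.protocol.duration >= first.duration_ms:
            raise ValidationError("stimulus must end before the sweep does")

    @property
    def rate(self) -> float:
        return self.sweeps[0].rate

    @property
    def kind(self) -> str:
        return self.sweeps[0].kind

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


def average_sweeps(s: SweepSet) -> Trace:
    """Point-wise arithmetic mean of all sweeps (the "averaged ripplet")."""
    data = np.stack([sw.samples for sw in s.sweeps])
    first = s.sweeps[0]
    return Trace(data.mean(axis=0), rate=first.rate, kind=first.kind,
                 holding=first.holding)


# ---------------------------------------------------------------------------
# Sweep-table CSV serialization
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = (
    "sample_rate_hz",
    "kind",
    "condition",
    "stim_onset_ms",
    "stim_duration_ms",
    "stim_intensity_frac",
)

_FLOAT_FMT = "{:.6f}"


def _fmt(x: float) -> str:
    return _FLOAT_FMT.format(float(x))


def write_sweepset(s: SweepSet, path: str | Path) -> None:
    """Serialize a SweepSet as a sweep-table CSV (UTF-8, LF, 6 decimals)."""
    path = Path(path)
    proto = s.protocol
    lines = [
        f"# sample_rate_hz={_fmt(s.rate)}",
        f"# kind={s.kind}",
        f"# condition={s.condition}",
        f"# stim_onset_ms={_fmt(proto.onset)}",
        f"# stim_duration_ms={_fmt(proto.duration)}",
        f"# stim_intensity_frac={_fmt(proto.intensity)}",
        f"# inter_trial_interval_s={_fmt(proto.inter_trial_interval)}",
    ]
    if s.sweeps[0].holding is not None:
        lines.append(f"# holding_mv={_fmt(s.sweeps[0].holding)}")
    for key in sorted(s.labels):
        lines.append(f"# label:{key}={s.labels[key]}")
    cols = ["time_ms"] + [f"sweep_{i:03d}" for i in range(s.n_sweeps)]
    lines.append(",".join(cols))
    times = s.sweeps[0].times_ms
    data = np.column_stack([times] + [sw.samples for sw in s.sweeps])
    for row in data:
        lines.append(",".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_sweepset(path: str | Path) -> SweepSet:
    """Parse a sweep-table CSV; metadata round-trips through write_sweepset."""
    path = Path(path)
    meta: dict[str, str] = {}
    labels: dict[str, str] = {}
    rows: list[list[float]] = []
    header_cols: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
                key, value = body.split("=", 1)
                key = key.strip()
                if key.startswith("label:"):
                    labels[key[len("label:"):]] = value
                else:
                    meta[key] = value
            elif header_cols is None:
                header_cols = line.split(",")
                if header_cols[0] != "time_ms":
                    raise FormatError(
                        f"{path}:{lineno}: first column must be time_ms"
                    )
            else:
                try:
                    rows.append([float(v) for v in line.split(",")])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad number ({exc})") from None
                if len(rows[-1]) != len(header_cols):
                    raise FormatError(
                        f"{path}:{lineno}: expected {len(header_cols)} columns, "
                        f"got {len(rows[-1])}"
                    )
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise FormatError(f"{path}: missing required header key {key!r}")
    if header_cols is None or not rows:
        raise FormatError(f"{path}: no data rows")
    if meta["condition"] not in CONDITIONS:
        raise FormatError(f"{path}: unknown condition {meta['condition']!r}")
    if meta["kind"] not in TRACE_KINDS:
        raise FormatError(f"{path}: unknown kind {meta['kind']!r}")

    data = np.asarray(rows)
    rate = float(meta["sample_rate_hz"])
    kind = meta["kind"]
    holding = float(meta["holding_mv"]) if "holding_mv" in meta else None
    if kind == "voltage_clamp" and holding is None:
        raise FormatError(f"{path}: voltage_clamp file missing holding_mv header")
    proto = StimulusProtocol(
        onset=float(meta["stim_onset_ms"]),
        duration=float(meta["stim_duration_ms"]),
        intensity=float(meta["stim_intensity_frac"]),
        inter_trial_interval=float(meta.get("inter_trial_interval_s", 8.0)),
    )
    sweeps = [
        Trace(data[:, j], rate=rate, kind=kind, holding=holding)
        for j in range(1, data.shape[1])
    ]
    return SweepSet(sweeps=sweeps, protocol=proto,
                    condition=meta["condition"], labels=labels)
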