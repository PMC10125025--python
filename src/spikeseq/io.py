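"""Reading, writing and validation of single-unit spike-train records.

Records arrive either as spike-time files (one timestamp per line) or as
interspike-interval (ISI) series (one duration per line). Internally all
records carry their ISIs in milliseconds; spike times are accepted in
seconds or milliseconds and converted on read.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("spikeseq")

#: Basal ganglia structures recorded in the source dataset.
STRUCTURES = ("GPe", "STN", "GPi")
#: Recording states: before and after MPTP-induced dopamine depletion.
STATES = ("normal", "MPTP")

#: Default analysis window, in ISIs.
DEFAULT_WINDOW = 5000


class SpikeDataError(ValueError):
    """Base class for malformed or invalid spike-train input."""


class ParseError(SpikeDataError):
    """A line of a spike file could not be parsed as a number."""


class ValidationError(SpikeDataError):
    """Parsed values violate a record invariant (ordering, positivity)."""


class InsufficientDataError(SpikeDataError):
    """Record too short for the requested analysis window."""


@dataclass(frozen=True)
class SpikeRecord:
    """One neuron's spike train, stored as an ISI series in milliseconds.

    Parameters
    ----------
    unit_id : str
        Label of the recorded unit.
    isis : np.ndarray
        Strictly positive ISI durations, ms.
    structure : str, optional
        One of ``GPe``, ``STN``, ``GPi`` (or "" when unknown).
    state : str, optional
        ``normal`` or ``MPTP`` (or "" when unknown).
    spike_times : np.ndarray, optional
        Original spike timestamps in seconds, if the record was built from
        spike times; consecutive differences equal ``isis`` (ms).
    """

    unit_id: str
    isis: np.ndarray
    structure: str = ""
    state: str = ""
    spike_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        isis = np.asarray(self.isis, dtype=float)
        object.__setattr__(self, "isis", isis)
        if isis.ndim != 1 or isis.size < 1:
            raise ValidationError(f"{self.unit_id}: need at least one ISI")
        if not np.all(isis > 0):
            raise ValidationError(f"{self.unit_id}: ISIs must be strictly positive")
        if self.structure and self.structure not in STRUCTURES:
            raise ValidationError(f"{self.unit_id}: unknown structure {self.structure!r}")
        if self.state and self.state not in STATES:
            raise ValidationError(f"{self.unit_id}: unknown state {self.state!r}")
        if self.spike_times is not None:
            t = np.asarray(self.spike_times, dtype=float)
            object.__setattr__(self, "spike_times", t)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(f"{self.unit_id}: spike times not strictly increasing")
            if not np.allclose(np.diff(t) * 1000.0, isis, rtol=1e-9, atol=1e-9):
                raise ValidationError(f"{self.unit_id}: spike times inconsistent with ISIs")

    @property
    def n_isis(self) -> int:
        return int(self.isis.size)


@dataclass(frozen=True)
class ManifestRow:
    path: str
    unit_id: str
    structure: str
    state: str


@dataclass
class Manifest:
    """Mapping from ISI/spike-time files to unit metadata."""

    rows: list[ManifestRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.unit_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({u for u in ids if ids.count(u) > 1})
            raise ValidationError(f"duplicate unit ids in manifest: {dupes}")
        for r in self.rows:
            if r.structure not in STRUCTURES:
                raise ValidationError(f"{r.unit_id}: unknown structure {r.structure!r}")
            if r.state not in STATES:
                raise ValidationError(f"{r.unit_id}: unknown state {r.state!r}")


def _parse_lines(path: Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: not a number: {s!r}") from None
    return np.asarray(values, dtype=float)


def read_record(
    path: str | Path,
    kind: str = "isis",
    units: str = "ms",
    unit_id: str | None = None,
    structure: str = "",
    state: str = "",
) -> SpikeRecord:
    """Read a plain-text spike-time or ISI file into a :class:`SpikeRecord`.

    Parameters
    ----------
    kind : {"times", "isis"}
        Whether lines are spike timestamps or ISI durations.
    units : {"s", "ms"}
        Units of the values in the file. Spike-time input is converted to
        ISIs in ms; ISI input in seconds is converted to ms.
    """
    path = Path(path)
    if kind not in ("times", "isis"):
        raise ValueError(f"kind must be 'times' or 'isis', got {kind!r}")
    if units not in ("s", "ms"):
        raise ValueError(f"units must be 's' or 'ms', got {units!r}")
    values = _parse_lines(path)
    uid = unit_id if unit_id is not None else path.stem
    if kind == "times":
        if values.size < 2:
            raise ValidationError(f"{path}: need at least two spike times")
        times_s = values if units == "s" else values / 1000.0
        diffs = np.diff(times_s)
        if np.any(diffs <= 0):
            k = int(np.argmax(diffs <= 0))
            raise ValidationError(
                f"{path}: spike times not strictly increasing at position {k + 1}"
            )
        return SpikeRecord(
            unit_id=uid,
            isis=diffs * 1000.0,
            structure=structure,
            state=state,
            spike_times=times_s,
        )
    if values.size < 1:
        raise ValidationError(f"{path}: need at least one ISI")
    isis_ms = values * 1000.0 if units == "s" else values
    if np.any(isis_ms <= 0):
        k = int(np.argmax(isis_ms <= 0))
        raise ValidationError(f"{path}: non-positive ISI at line {k + 1}")
    return SpikeRecord(unit_id=uid, isis=isis_ms, structure=structure, state=state)


def write_record(record: SpikeRecord, path: str | Path) -> None:
    """Write a record as a canonical ISI text file (ms, one value per line).

    Uses ``repr`` precision so that a write/read round trip reproduces the
    ISI array bit-identically.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for v in record.isis:
            fh.write(f"{float(v)!r}\n")


def read_manifest(path: str | Path) -> Manifest:
    """Read a CSV manifest with header ``path,unit_id,structure,state``."""
    path = Path(path)
    rows: list[ManifestRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"path", "unit_id", "structure", "state"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: manifest must have columns {sorted(required)}")
        for row in reader:
            rows.append(
                ManifestRow(
                    path=row["path"],
                    unit_id=row["unit_id"],
                    structure=row["structure"],
                    state=row["state"],
                )
            )
    return Manifest(rows=rows)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "unit_id", "structure", "state"])
        for r in manifest.rows:
            writer.writerow([r.path, r.unit_id, r.structure, r.state])


def analysis_window(record: SpikeRecord, n: int = DEFAULT_WINDOW) -> SpikeRecord:
    """Restrict a record to its first ``n`` ISIs.

    Records shorter than the window do not enter the analysis; an
    :class:`InsufficientDataError` is raised so batch drivers can skip them.
    """
    if record.n_isis < n:
        raise InsufficientDataError(
            f"{record.unit_id}: {record.n_isis} ISIs < window of {n}"
        )
    if record.n_isis == n:
        return record
    return replace(
        record,
        isis=record.isis[:n],
        spike_times=record.spike_times[: n + 1] if record.spike_times is not None else None,
    )


def basic_stats(record: SpikeRecord) -> tuple[int, float, float, float]:
    """Return ``(n_isis, duration_s, rate_spk_per_s, cv)``.

    Duration is the summed ISI time; the rate counts spikes, i.e.
    ``(n_isis + 1) / duration``; CV uses the sample (n-1) standard deviation.
    """
    isis = record.isis
    if isis.size < 2:
        raise ValidationError(f"{record.unit_id}: need >=2 ISIs for basic stats")
    duration_s = float(np.sum(isis)) / 1000.0
    rate = (isis.size + 1) / duration_s
    cv = float(np.std(isis, ddof=1) / np.mean(isis))
    return isis.size, duration_s, rate, cv


def load_dataset(
    manifest: Manifest,
    base_dir: str | Path = ".",
    kind: str = "isis",
    units: str = "ms",
    window: int | None = DEFAULT_WINDOW,
) -> list[SpikeRecord]:
    """Load and window all manifest records, skipping short ones with a warning."""
    base = Path(base_dir)
    records: list[SpikeRecord] = []
    for row in manifest.rows:
        rec = read_record(
            base / row.path, kind=kind, units=units,
            unit_id=row.unit_id, structure=row.structure, state=row.state,
        )
        if window is not None:
            try:
                rec = analysis_window(rec, window)
            except InsufficientDataError as exc:
                logger.warning("skipping %s: %s", row.unit_id, exc)
                continue
        records.append(rec)
    return records


def records_to_windowed(records: Iterable[SpikeRecord], n: int) -> list[SpikeRecord]:
    """Window each record, silently dropping the too-short ones."""
    out = []
    for rec in records:
        try:
            out.append(analysis_window(rec, n))
        except InsufficientDataError:
            logger.warning("skipping %s: fewer than %d ISIs", rec.unit_id, n)
    return out
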