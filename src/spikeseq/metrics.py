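"""Per-cell summary statistics over detected ISI-sequence annotations.

All medians use the midpoint convention for even counts (numpy default);
metrics that are undefined for a cell (e.g. no 2-ISI family) are returned
as ``nan`` and treated as missing downstream.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .detect import SequenceAnnotation

#: Peri-sequence profile half-window, in ISIs.
PERI_WINDOW = 25


def proportion_isis_in_sequences(annotation: SequenceAnnotation) -> float:
    """Fraction of analyzed ISIs covered by a retained sequence occurrence."""
    if annotation.n_isis == 0:
        return float("nan")
    return float(np.mean(annotation.mask))


def proportion_time_in_sequences(
    annotation: SequenceAnnotation, isis: np.ndarray
) -> float:
    """Fraction of record time covered by retained sequence occurrences."""
    isis = np.asarray(isis, dtype=float)
    total = float(np.sum(isis))
    if total == 0:
        return float("nan")
    return float(np.sum(isis[annotation.mask])) / total


def _two_isi_families(annotation: SequenceAnnotation):
    return [f for f in annotation.families if f.length == 2]


def two_isi_durations(annotation: SequenceAnnotation, isis: np.ndarray) -> list[float]:
    """Durations (ms) of every retained occurrence of every 2-ISI family."""
    isis = np.asarray(isis, dtype=float)
    out: list[float] = []
    for f in _two_isi_families(annotation):
        for s in f.occurrence_starts:
            out.append(float(isis[s] + isis[s + 1]))
    return out


def median_2isi_duration(annotation: SequenceAnnotation, isis: np.ndarray) -> float:
    durs = two_isi_durations(annotation, isis)
    return float(np.median(durs)) if durs else float("nan")


def max_repetitions_2isi(annotation: SequenceAnnotation) -> int:
    """Maximal occurrence count over 2-ISI families (template counts as one)."""
    fams = _two_isi_families(annotation)
    return max((f.n_occurrences for f in fams), default=0)


def norm_interseq_spacing(annotation: SequenceAnnotation, n: int) -> float:
    """Median intersequence spacing of 2-ISI families, normalized to chance.

    Per family: gaps between consecutive occurrences (end of one to start
    of the next, in ISIs), divided by the spacing expected if the record's
    uncovered ISIs were split evenly between the occurrences. Values < 1
    indicate clustering. Median over families; ``nan`` when undefined.
    """
    values: list[float] = []
    for f in _two_isi_families(annotation):
        starts = f.occurrence_starts
        if len(starts) < 2:
            continue
        L = f.length
        gaps = [starts[k + 1] - starts[k] - L for k in range(len(starts) - 1)]
        expected = (n - len(starts) * L) / len(starts)
        if expected <= 0:
            continue  # full coverage: expected spacing undefined
        values.append(float(np.median(gaps)) / expected)
    return float(np.median(values)) if values else float("nan")


def peri_sequence_profile(
    isis: np.ndarray, annotation: SequenceAnnotation, window: int = PERI_WINDOW
) -> np.ndarray:
    """Median normalized-ISI profile around 2-ISI sequence occurrences.

    For every retained occurrence, extracts positions ``-window .. -1``,
    the two in-sequence ISIs, and ``+1 .. +window``, each ISI divided by
    the cell's median ISI. Out-of-range positions are missing; the profile
    is the per-position median over occurrences ignoring missing values.
    Returns an array of length ``2 * window + 2`` (nan where no occurrence
    contributes).
    """
    isis = np.asarray(isis, dtype=float)
    med = float(np.median(isis))
    starts = [s for f in _two_isi_families(annotation) for s in f.occurrence_starts]
    width = 2 * window + 2
    if not starts:
        return np.full(width, np.nan)
    rows = np.full((len(starts), width), np.nan)
    n = isis.size
    for r, s in enumerate(starts):
        lo = s - window
        for p in range(width):
            k = lo + p
            if 0 <= k < n:
                rows[r, p] = isis[k] / med
    with warnings.catch_warnings():
        # positions unreachable from every occurrence are legitimately all-nan
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(rows, axis=0)


def first_isi_norm(annotation: SequenceAnnotation, isis: np.ndarray) -> float:
    """Median over 2-ISI families of (template first ISI / cell median ISI)."""
    isis = np.asarray(isis, dtype=float)
    med = float(np.median(isis))
    vals = [float(f.template_isis[0]) / med for f in _two_isi_families(annotation)]
    return float(np.median(vals)) if vals else float("nan")


def second_first_ratio(annotation: SequenceAnnotation) -> float:
    """Median over 2-ISI families of (template second ISI / first ISI)."""
    vals = [
        float(f.template_isis[1]) / float(f.template_isis[0])
        for f in _two_isi_families(annotation)
    ]
    return float(np.median(vals)) if vals else float("nan")


def sequence_length_histogram(annotation: SequenceAnnotation) -> dict[int, int]:
    """Count of unique retained families per sequence length."""
    return dict(Counter(f.length for f in annotation.families))


def n_families(annotation: SequenceAnnotation) -> int:
    return len(annotation.families)


#: Registry of scalar per-cell metrics computed from (annotation, isis).
#: These are the quantities recomputed on shuffled surrogates.
METRIC_FUNCS = {
    "prop_isis_in_seq": lambda ann, isis: proportion_isis_in_sequences(ann),
    "prop_time_in_seq": proportion_time_in_sequences,
    "median_2isi_duration": median_2isi_duration,
    "max_repetitions_2isi": lambda ann, isis: float(max_repetitions_2isi(ann)),
    "norm_interseq_spacing": lambda ann, isis: norm_interseq_spacing(ann, len(isis)),
    "first_isi_norm": first_isi_norm,
    "second_first_ratio": lambda ann, isis: second_first_ratio(ann),
    "n_families": lambda ann, isis: float(n_families(ann)),
}


def compute_metrics(
    annotation: SequenceAnnotation,
    isis: np.ndarray,
    names: Iterable[str] | None = None,
) -> dict[str, float]:
    names = list(METRIC_FUNCS) if names is None else list(names)
    return {name: float(METRIC_FUNCS[name](annotation, isis)) for name in names}


@dataclass
class CellSummary:
    """All per-cell sequence/burst metrics plus their null ratios."""

    unit_id: str
    structure: str
    state: str
    n_isis_analyzed: int
    firing_rate: float = float("nan")
    cv: float = float("nan")
    metrics: dict[str, float] = field(default_factory=dict)
    null_medians: dict[str, float] = field(default_factory=dict)
    null_ratios: dict[str, float] = field(default_factory=dict)
    seq_length_hist: dict[int, int] = field(default_factory=dict)
    prop_isis_in_bursts: float = float("nan")
    frac_seq_in_burst: float = float("nan")
    frac_burst_in_seq: float = float("nan")

    def to_row(self) -> dict[str, float | int | str]:
        row: dict[str, float | int | str] = {
            "unit_id": self.unit_id,
            "structure": self.structure,
            "state": self.state,
            "n_isis_analyzed": self.n_isis_analyzed,
            "firing_rate": self.firing_rate,
            "cv": self.cv,
            "prop_isis_in_bursts": self.prop_isis_in_bursts,
            "frac_seq_in_burst": self.frac_seq_in_burst,
            "frac_burst_in_seq": self.frac_burst_in_seq,
        }
        for k, v in self.metrics.items():
            row[k] = v
        for k, v in self.null_medians.items():
            row[f"{k}_null_median"] = v
        for k, v in self.null_ratios.items():
            row[f"{k}_null_ratio"] = v
        for L in sorted(self.seq_length_hist):
            row[f"n_seqs_len{L}"] = self.seq_length_hist[L]
        return row


def summaries_to_frame(summaries: Iterable[CellSummary]) -> pd.DataFrame:
    """Tidy one-row-per-cell table of all metrics and null ratios."""
    return pd.DataFrame([s.to_row() for s in summaries])
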