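"""Detection of exactly repeating ISI sequences under a tolerance criterion.

A *sequence family* is a run of ``L >= 2`` consecutive ISIs (the template,
at its earliest position in the record) together with every later stretch of
``L`` ISIs whose elements each lie within a fractional tolerance of the
*corresponding template element*. Matching is always against the template,
never chained occurrence-to-occurrence (the tolerance relation is not
transitive).

The detector runs in three stages:

1. candidate scan over anchor pairs ``(i, j)``: forward-maximal,
   left-maximal matching runs (numba-accelerated);
2. family formation: candidates grouped to their earliest occurrence, one
   family per (template, run length), occurrences kept disjoint greedily;
3. longest-first retention: families claim ISI indices in decreasing length
   order; an occurrence sharing any index with an already retained
   occurrence is discarded, and a family surviving with fewer than two
   occurrences is removed and claims nothing.

Full containment of a shorter sequence inside a longer one is a special
case of overlap, so stage 3 subsumes containment pruning: occurrences of a
shorter family inside a *retained* longer occurrence are discarded, while
isolated extra occurrences survive if at least two remain. Crucially, a
longer family that is itself discarded does not shadow shorter families.
A standalone :func:`prune_contained` is provided for analyses that want
the containment relation in isolation.

The result is an annotation with pairwise-disjoint retained occurrences and
a per-ISI coverage mask.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .io import DEFAULT_WINDOW, SpikeRecord, analysis_window


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the sequence detector.

    Parameters
    ----------
    tolerance_mode : {"relative", "absolute_ms"}
        ``relative``: accept ``|x - t| <= tolerance_value * t`` against
        template element ``t``. ``absolute_ms``: the value is a maximal
        timing error in ms, converted to a per-cell relative tolerance by
        dividing by the cell's median ISI.
    tolerance_value : float
        Fraction (default 0.01, i.e. 1%) or ms, depending on the mode.
    min_length : int
        Minimum sequence length in ISIs (default 2, i.e. three spikes).
    window : int or None
        Analysis window in ISIs (default 5000); ``None`` analyses the whole
        record.
    """

    tolerance_mode: str = "relative"
    tolerance_value: float = 0.01
    min_length: int = 2
    window: int | None = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.tolerance_mode not in ("relative", "absolute_ms"):
            raise ValueError(f"unknown tolerance_mode {self.tolerance_mode!r}")
        if not self.tolerance_value > 0:
            raise ValueError("tolerance_value must be > 0")
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")


@dataclass
class SequenceFamily:
    """A template ISI run plus the start indices of all retained repetitions.

    ``occurrence_starts`` initially begins with ``template_start``; pruning
    stages may remove the template occurrence itself while the family (its
    pattern) survives through other occurrences.
    """

    template_start: int
    length: int
    occurrence_starts: list[int]
    template_isis: np.ndarray

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrence_starts)

    def intervals(self) -> list[tuple[int, int]]:
        """Half-open ISI index ranges ``[s, s + length)`` of occurrences."""
        return [(s, s + self.length) for s in self.occurrence_starts]


@dataclass
class SequenceAnnotation:
    """Retained families plus the per-ISI coverage mask for one record."""

    mask: np.ndarray
    families: list[SequenceFamily] = field(default_factory=list)

    @property
    def n_isis(self) -> int:
        return int(self.mask.size)

    def coverage_fraction(self) -> float:
        return float(np.mean(self.mask)) if self.mask.size else 0.0

    def to_json(self) -> str:
        payload = {
            "n_isis": self.n_isis,
            "families": [
                {
                    "template_start": int(f.template_start),
                    "length": int(f.length),
                    "occurrence_starts": [int(s) for s in f.occurrence_starts],
                    "template_isis": [float(v) for v in f.template_isis],
                }
                for f in self.families
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SequenceAnnotation":
        payload = json.loads(text)
        families = [
            SequenceFamily(
                template_start=f["template_start"],
                length=f["length"],
                occurrence_starts=list(f["occurrence_starts"]),
                template_isis=np.asarray(f["template_isis"], dtype=float),
            )
            for f in payload["families"]
        ]
        mask = np.zeros(payload["n_isis"], dtype=bool)
        for f in families:
            for s, e in f.intervals():
                mask[s:e] = True
        return cls(mask=mask, families=families)

    def write_mask_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("isi_index,in_sequence\n")
            for k, v in enumerate(self.mask):
                fh.write(f"{k},{int(v)}\n")


def tolerance_for(cell_isis: np.ndarray, config: DetectionConfig) -> float:
    """Effective relative tolerance for one cell.

    In ``absolute_ms`` mode the ms bound is scaled by the cell's median ISI,
    yielding a proportional cutoff with the requested maximal timing error
    at the median.
    """
    cell_isis = np.asarray(cell_isis, dtype=float)
    if cell_isis.size == 0:
        raise ValueError("empty ISI sequence")
    if config.tolerance_mode == "relative":
        return float(config.tolerance_value)
    med = float(np.median(cell_isis))
    if med == 0:
        raise ValueError("zero median ISI")
    return float(config.tolerance_value) / med


def match_run_length(isis: Sequence[float], i: int, j: int, tol: float) -> int:
    """Length of the matching run anchored at template ``i``, occurrence ``j``.

    Largest ``L`` such that ``|isis[j+k] - isis[i+k]| <= tol * isis[i+k]``
    for all ``k < L``; comparison is always against the ISIs at ``i``.
    """
    if not i < j:
        raise ValueError("need i < j")
    isis = np.asarray(isis, dtype=float)
    n = isis.size
    L = 0
    while j + L < n and abs(isis[j + L] - isis[i + L]) <= tol * isis[i + L]:
        L += 1
    return L


@njit(cache=True)
def _scan_pairs(isis, tol, min_len):  # pragma: no cover - exercised via wrapper
    """All left-maximal anchor pairs with forward-maximal run length >= min_len.

    Returns parallel arrays (template index, occurrence index, run length),
    ordered by template then occurrence index.
    """
    n = isis.size
    cap = 1024
    out_i = np.empty(cap, np.int64)
    out_j = np.empty(cap, np.int64)
    out_l = np.empty(cap, np.int64)
    cnt = 0
    for i in range(n - 1):
        for j in range(i + 1, n - min_len + 1):
            if i > 0 and abs(isis[j - 1] - isis[i - 1]) <= tol * isis[i - 1]:
                continue  # interior of a longer run anchored one step earlier
            if abs(isis[j] - isis[i]) > tol * isis[i]:
                continue
            L = 1
            while j + L < n and abs(isis[j + L] - isis[i + L]) <= tol * isis[i + L]:
                L += 1
            if L >= min_len:
                if cnt == cap:
                    cap *= 2
                    tmp_i = np.empty(cap, np.int64)
                    tmp_j = np.empty(cap, np.int64)
                    tmp_l = np.empty(cap, np.int64)
                    tmp_i[:cnt] = out_i[:cnt]
                    tmp_j[:cnt] = out_j[:cnt]
                    tmp_l[:cnt] = out_l[:cnt]
                    out_i, out_j, out_l = tmp_i, tmp_j, tmp_l
                out_i[cnt] = i
                out_j[cnt] = j
                out_l[cnt] = L
                cnt += 1
    return out_i[:cnt], out_j[:cnt], out_l[:cnt]


def find_sequence_families(
    isis: np.ndarray, config: DetectionConfig, tol: float | None = None
) -> list[SequenceFamily]:
    """Enumerate repeating-sequence families before cross-family pruning.

    Candidates are grouped to their earliest occurrence: a candidate pair
    ``(i, j)`` of run length ``L`` is suppressed when an already-formed
    family of length >= ``L`` holds both ``i`` and ``j`` as occurrence
    starts (the repetition of a known pattern does not seed a new family,
    but a strictly longer pattern starting at a repetition index still can).
    Occurrences within a family are kept disjoint greedily left-to-right.
    """
    isis = np.asarray(isis, dtype=float)
    min_len = config.min_length
    if isis.size < 2 * min_len:
        return []
    if tol is None:
        tol = tolerance_for(isis, config)
    ii, jj, ll = _scan_pairs(isis, float(tol), int(min_len))

    by_template: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for k in range(ii.size):
        by_template[int(ii[k])].append((int(jj[k]), int(ll[k])))

    families: list[SequenceFamily] = []
    occ_sets: list[set[int]] = []  # parallel to families, for suppression
    for i in sorted(by_template):
        cand = [
            (j, L)
            for j, L in by_template[i]
            if not any(
                fam.length >= L and i in occ and j in occ
                for fam, occ in zip(families, occ_sets)
            )
        ]
        if not cand:
            continue
        prev_kept: tuple[int, ...] | None = None
        for L in sorted({L for _, L in cand}, reverse=True):
            occ = [i] + [j for j, Lj in cand if Lj >= L]
            kept: list[int] = []
            last_end = -1
            for s in occ:
                if s >= last_end:
                    kept.append(s)
                    last_end = s + L
            if len(kept) < 2:
                continue
            if prev_kept is not None and tuple(kept) == prev_kept:
                # identical occurrence set at a shorter length: strictly
                # contained in the family just emitted, never survives
                continue
            prev_kept = tuple(kept)
            families.append(
                SequenceFamily(
                    template_start=i,
                    length=L,
                    occurrence_starts=kept,
                    template_isis=isis[i : i + L].copy(),
                )
            )
            occ_sets.append(set(kept))
    return families


class _IntervalCover:
    """Query whether [s, e) lies inside any of a fixed set of intervals."""

    def __init__(self, intervals: list[tuple[int, int]]):
        intervals = sorted(intervals)
        self.starts = [s for s, _ in intervals]
        # prefix max of ends: the best right edge among intervals
        # starting at or before a query point
        self.max_ends: list[int] = []
        best = -1
        for _, e in intervals:
            best = max(best, e)
            self.max_ends.append(best)

    def contains(self, s: int, e: int) -> bool:
        k = bisect_right(self.starts, s)
        return k > 0 and self.max_ends[k - 1] >= e


def prune_contained(families: list[SequenceFamily]) -> list[SequenceFamily]:
    """Drop occurrences fully contained in an occurrence of a longer family.

    Containment is judged against all occurrences of strictly longer
    families as originally found. A family survives only if at least two
    non-contained occurrences remain.

    The full detection pipeline does not call this: :func:`resolve_overlaps`
    already discards contained occurrences (containment implies overlap)
    while correctly ignoring longer families that are themselves discarded.
    This standalone form exposes the containment relation on its own.
    """
    if not families:
        return []
    intervals_by_len: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for f in families:
        intervals_by_len[f.length].extend(f.intervals())
    lengths = sorted(intervals_by_len, reverse=True)

    out: list[SequenceFamily] = []
    cover = _IntervalCover([])
    prev_len: int | None = None
    acc: list[tuple[int, int]] = []
    for L in lengths:
        # intervals of families strictly longer than L
        if prev_len is not None:
            acc.extend(intervals_by_len[prev_len])
            cover = _IntervalCover(acc)
        prev_len = L
        for f in [g for g in families if g.length == L]:
            kept = [s for s in f.occurrence_starts if not cover.contains(s, s + L)]
            if len(kept) >= 2:
                out.append(replace(f, occurrence_starts=kept))
    return out


def resolve_overlaps(
    families: list[SequenceFamily], n_isis: int
) -> SequenceAnnotation:
    """Resolve cross-family overlaps (and containment) in favour of longer
    sequences.

    Families are processed in decreasing length (ties: more occurrences
    first, then smaller template start). An occurrence sharing any ISI
    index with an already retained occurrence is discarded; a family
    dropping below two occurrences is removed and claims nothing.
    """
    order = sorted(
        families, key=lambda f: (-f.length, -f.n_occurrences, f.template_start)
    )
    mask = np.zeros(n_isis, dtype=bool)
    retained: list[SequenceFamily] = []
    for f in order:
        kept = [
            s for s in f.occurrence_starts if not mask[s : s + f.length].any()
        ]
        if len(kept) < 2:
            continue
        for s in kept:
            mask[s : s + f.length] = True
        retained.append(replace(f, occurrence_starts=kept))
    return SequenceAnnotation(mask=mask, families=retained)


def detect(record: SpikeRecord, config: DetectionConfig) -> SequenceAnnotation:
    """Full detection pipeline: window -> scan -> longest-first retention."""
    if config.window is not None:
        record = analysis_window(record, config.window)
    return detect_isis(record.isis, config)


def detect_isis(isis: np.ndarray, config: DetectionConfig) -> SequenceAnnotation:
    """Detection on a bare ISI array (already windowed)."""
    isis = np.asarray(isis, dtype=float)
    tol = tolerance_for(isis, config)
    families = find_sequence_families(isis, config, tol=tol)
    return resolve_overlaps(families, isis.size)
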