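"""Orchestration of the full per-cell and group-level analysis.

``run_cell`` composes the per-cell stages — windowing, sequence detection,
metrics, shuffle null, burst detection and overlap — and ``run_study``
applies them across a dataset and produces the group-comparison tables.
``tolerance_sweep`` and ``segment_stability`` are the methodological
sweeps used to justify the default threshold and window length.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bursts import (
    DEFAULT_SURPRISE_CUTOFF,
    detect_bursts,
    overlap_metrics,
    rate_and_burst_regressions,
)
from .detect import DetectionConfig, detect_isis
from .groupstats import run_group_table, summary_table_markdown
from .io import (
    InsufficientDataError,
    Manifest,
    SpikeRecord,
    analysis_window,
    basic_stats,
    load_dataset,
    read_manifest,
)
from .metrics import (
    CellSummary,
    compute_metrics,
    sequence_length_histogram,
    summaries_to_frame,
)
from .nullmodel import DEFAULT_N_SHUFFLES, null_distribution, ratio_to_null

logger = logging.getLogger("spikeseq")

#: Thresholds of the sweep analyses (fractional tolerance).
SWEEP_TOLERANCES = (0.001, 0.005, 0.01, 0.05, 0.1)
#: Segment lengths of the stability analysis, in ISIs.
STABILITY_LENGTHS = (500, 1000, 2000, 5000, 10000, 20000)


@dataclass
class RunConfig:
    """Parameters of a full study run."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    n_shuffles: int = DEFAULT_N_SHUFFLES
    burst_cutoff: float = DEFAULT_SURPRISE_CUTOFF
    seed: int = 0
    tolerances: tuple[float, ...] = SWEEP_TOLERANCES


def run_cell(
    record: SpikeRecord,
    config: DetectionConfig,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | int | None = None,
    burst_cutoff: float = DEFAULT_SURPRISE_CUTOFF,
) -> CellSummary:
    """Full per-cell pipeline: detection, metrics, null ratios, bursts."""
    t0 = time.perf_counter()
    if config.window is not None:
        record = analysis_window(record, config.window)
    isis = record.isis
    n_isis, duration_s, rate, cv = basic_stats(record)

    ann = detect_isis(isis, config)
    original = compute_metrics(ann, isis)

    nulls = null_distribution(
        isis,
        config,
        n_shuffles=n_shuffles,
        rng=rng,
    )
    null_medians = {name: d.null_median for name, d in nulls.items()}
    null_ratios = {
        name: ratio_to_null(original[name], d) for name, d in nulls.items()
    }

    burst_set = detect_bursts(isis, cutoff=burst_cutoff, rate=rate)
    frac_seq_in_burst, frac_burst_in_seq = overlap_metrics(
        ann.mask, burst_set.burst_isi_mask
    )

    summary = CellSummary(
        unit_id=record.unit_id,
        structure=record.structure,
        state=record.state,
        n_isis_analyzed=n_isis,
        firing_rate=rate,
        cv=cv,
        metrics=original,
        null_medians=null_medians,
        null_ratios=null_ratios,
        seq_length_hist=sequence_length_histogram(ann),
        prop_isis_in_bursts=burst_set.prop_isis_in_bursts(),
        frac_seq_in_burst=frac_seq_in_burst,
        frac_burst_in_seq=frac_burst_in_seq,
    )
    logger.info(
        "%s: prop_isis=%.3f ratio=%.2f bursts=%d (%.1fs)",
        record.unit_id,
        original["prop_isis_in_seq"],
        null_ratios["prop_isis_in_seq"]
        if not np.isnan(null_ratios["prop_isis_in_seq"])
        else float("nan"),
        burst_set.n_bursts,
        time.perf_counter() - t0,
    )
    return summary


def tolerance_sweep(
    record: SpikeRecord,
    tolerances: tuple[float, ...] = SWEEP_TOLERANCES,
    lengths: tuple[int, ...] = (1000, 2000, 5000),
) -> pd.DataFrame:
    """Proportion of ISIs in sequences per (tolerance, window length).

    At fixed length the proportion is non-decreasing in tolerance (the
    candidate set only grows with the threshold).
    """
    rows = []
    for n in lengths:
        if record.n_isis < n:
            logger.warning("sweep: record %s shorter than %d ISIs; skipped", record.unit_id, n)
            continue
        isis = record.isis[:n]
        for tol in tolerances:
            cfg = DetectionConfig(
                tolerance_mode="relative", tolerance_value=tol, window=None
            )
            ann = detect_isis(isis, cfg)
            rows.append(
                {
                    "tolerance": tol,
                    "length": n,
                    "prop_isis_in_seq": float(np.mean(ann.mask)),
                }
            )
    return pd.DataFrame(rows)


def segment_stability(
    record: SpikeRecord,
    segment_lengths: tuple[int, ...] = STABILITY_LENGTHS,
    config: DetectionConfig | None = None,
) -> dict[int, list[float]]:
    """Per-segment sequence proportions for nonoverlapping segments.

    Each length yields ``floor(N / length)`` consecutive segments analyzed
    independently; the spread across segments measures the stability of
    the estimate at that window length.
    """
    if config is None:
        config = DetectionConfig(window=None)
    out: dict[int, list[float]] = {}
    for n in segment_lengths:
        n_segments = record.n_isis // n
        if n_segments == 0:
            logger.warning(
                "stability: record %s shorter than segment length %d; skipped",
                record.unit_id,
                n,
            )
            continue
        props = []
        for k in range(n_segments):
            seg = record.isis[k * n : (k + 1) * n]
            ann = detect_isis(seg, config)
            props.append(float(np.mean(ann.mask)))
        out[n] = props
    return out


def run_study(
    records: list[SpikeRecord] | Manifest | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    base_dir: str | Path = ".",
    units: str = "ms",
) -> dict:
    """Run the complete analysis over a dataset.

    Accepts in-memory records, a Manifest, or a manifest CSV path. Records
    shorter than the analysis window are skipped with a warning; the run
    fails only when no usable record remains. Writes per-cell and
    group-comparison CSVs, a markdown summary table and a run manifest
    when ``out_dir`` is given.
    """
    if config is None:
        config = RunConfig()
    if isinstance(records, (str, Path)):
        records = read_manifest(records)
    if isinstance(records, Manifest):
        records = load_dataset(
            records, base_dir=base_dir, units=units, window=config.detection.window
        )

    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(records))
    summaries: list[CellSummary] = []
    for rec, child in zip(records, children):
        try:
            summaries.append(
                run_cell(
                    rec,
                    config.detection,
                    n_shuffles=config.n_shuffles,
                    rng=np.random.default_rng(child),
                    burst_cutoff=config.burst_cutoff,
                )
            )
        except InsufficientDataError as exc:
            logger.warning("skipping %s: %s", rec.unit_id, exc)
    if not summaries:
        raise InsufficientDataError("no usable records in the dataset")

    cells = summaries_to_frame(summaries)
    groups = run_group_table(
        cells,
        metrics=[
            "prop_isis_in_seq",
            "prop_time_in_seq",
            "median_2isi_duration",
            "max_repetitions_2isi",
            "norm_interseq_spacing",
        ],
    )
    regressions = rate_and_burst_regressions(cells)
    summary_md = summary_table_markdown(
        cells, ["firing_rate", "cv", "prop_isis_in_seq", "prop_time_in_seq"]
    )

    bundle = {
        "cells": cells,
        "groups": groups,
        "regressions": regressions,
        "summary_markdown": summary_md,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cells.to_csv(out / "cells.csv", index=False)
        groups.to_csv(out / "group_comparisons.csv", index=False)
        regressions.to_csv(out / "regressions.csv", index=False)
        (out / "summary_table.md").write_text(summary_md + "\n")
        run_manifest = {
            "version": __version__,
            "seed": config.seed,
            "n_shuffles": config.n_shuffles,
            "burst_cutoff": config.burst_cutoff,
            "detection": {
                "tolerance_mode": config.detection.tolerance_mode,
                "tolerance_value": config.detection.tolerance_value,
                "min_length": config.detection.min_length,
                "window": config.detection.window,
            },
            "n_cells": len(summaries),
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(run_manifest, fh, indent=1)
    return bundle
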