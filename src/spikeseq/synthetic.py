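"""Synthetic spike-train generator with known ground truth.

The generator produces the statistical structure the analysis assumes:

* a gamma-renewal ISI background matched to a target firing rate and CV
  (the two marginal statistics that characterize the recorded populations);
* optionally, planted repeating ISI motifs with controlled multiplicative
  jitter and either uniform or clustered placement, returning the true
  occurrence positions for detector validation;
* optionally, burst epochs: contiguous stretches whose ISIs are shortened
  by a rate multiplier, for exercising the surprise burst detector.

Group presets follow the recorded populations' median rate/CV per
structure and state (GPe/STN/GPi, normal/MPTP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import Manifest, ManifestRow, SpikeRecord, write_manifest, write_record


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic spike train.

    Parameters
    ----------
    n_isis : int
        Number of ISIs to generate.
    rate : float
        Target mean firing rate, spikes/s (mean ISI = 1000/rate ms).
    cv : float
        Target coefficient of variation of ISIs; gamma shape = 1/cv^2.
    motif : tuple of float, optional
        ISI motif (ms, length >= 2) to plant.
    n_motif_occurrences : int
        Number of disjoint planted copies (including the first).
    motif_jitter : float
        Relative jitter: each planted element is multiplied by
        ``1 + u``, ``u ~ U(-jitter, +jitter)`` independently.
    motif_placement : {"uniform", "clustered"}
        Uniform: occurrence starts drawn uniformly among disjoint
        placements. Clustered: occurrences packed into one block with
        gaps of 0-2 background ISIs.
    burst_epochs : tuple (count, rate_multiplier, duration_s), optional
        Insert ``count`` epochs whose ISIs are divided by the multiplier.
    seed : int
        Generator seed.
    """

    n_isis: int = 5000
    rate: float = 60.0
    cv: float = 1.0
    motif: tuple[float, ...] | None = None
    n_motif_occurrences: int = 0
    motif_jitter: float = 0.0
    motif_placement: str = "uniform"
    burst_epochs: tuple[int, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.cv <= 0:
            raise ValueError("rate and cv must be > 0")
        if self.motif_jitter < 0:
            raise ValueError("motif_jitter must be >= 0")
        if self.motif is not None:
            if len(self.motif) < 2 or any(v <= 0 for v in self.motif):
                raise ValueError("motif needs >= 2 strictly positive ISIs")
        if self.motif_placement not in ("uniform", "clustered"):
            raise ValueError(f"unknown motif_placement {self.motif_placement!r}")


def gen_renewal(
    spec: GeneratorSpec, rng: np.random.Generator | None = None, unit_id: str = "synthetic"
) -> SpikeRecord:
    """Gamma-renewal ISI stream with the spec's rate and CV."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = 1.0 / spec.cv**2
    mean_isi_ms = 1000.0 / spec.rate
    scale = mean_isi_ms / shape
    isis = rng.gamma(shape, scale, size=spec.n_isis)
    # gamma variates are almost surely positive; clip defensively against
    # underflow to zero at extreme CVs
    isis = np.maximum(isis, 1e-9)
    return SpikeRecord(unit_id=unit_id, isis=isis)


def _draw_disjoint_starts(
    n: int, n_occ: int, L: int, rng: np.random.Generator
) -> list[int]:
    """Sorted starts with pairwise spacing >= L, uniform over placements."""
    slack = n - n_occ * L
    if slack < 0:
        raise ValueError(
            f"cannot place {n_occ} disjoint motifs of length {L} in {n} ISIs"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n_occ))
    return [int(offsets[k] + k * L) for k in range(n_occ)]


def _draw_clustered_starts(
    n: int, n_occ: int, L: int, rng: np.random.Generator
) -> list[int]:
    """Occurrences packed into one block, gaps of 0-2 background ISIs."""
    gaps = rng.integers(0, 3, size=n_occ - 1) if n_occ > 1 else np.array([], int)
    block = n_occ * L + int(np.sum(gaps))
    if block > n:
        raise ValueError("clustered motif block does not fit the record")
    b = int(rng.integers(0, n - block + 1))
    starts = [b]
    for g in gaps:
        starts.append(starts[-1] + L + int(g))
    return starts


def plant_motifs(
    record: SpikeRecord, spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> tuple[SpikeRecord, list[int]]:
    """Overwrite disjoint stretches with jittered copies of the motif.

    Returns the modified record and the true occurrence start indices
    (sorted). With jitter ``j`` and detection tolerance ``tol``, every
    planted occurrence matches the earliest one whenever
    ``2 j <= tol (1 - j)`` — guaranteed in particular at ``j <= tol / (2 + tol)``.
    """
    if spec.motif is None or spec.n_motif_occurrences < 1:
        return record, []
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    motif = np.asarray(spec.motif, dtype=float)
    L = motif.size
    n = record.n_isis
    if spec.motif_placement == "uniform":
        starts = _draw_disjoint_starts(n, spec.n_motif_occurrences, L, rng)
    else:
        starts = _draw_clustered_starts(n, spec.n_motif_occurrences, L, rng)
    isis = record.isis.copy()
    for s in starts:
        u = rng.uniform(-spec.motif_jitter, spec.motif_jitter, size=L)
        isis[s : s + L] = motif * (1.0 + u)
    return replace(record, isis=isis, spike_times=None), starts


def apply_burst_epochs(
    record: SpikeRecord, spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> tuple[SpikeRecord, list[tuple[int, int]]]:
    """Divide the ISIs of ``count`` disjoint epochs by the rate multiplier.

    Epoch length in ISIs is chosen so the accelerated epoch spans roughly
    ``duration_s``; returns the modified record and the epoch index ranges.
    """
    if spec.burst_epochs is None:
        return record, []
    count, mult, duration_s = spec.burst_epochs
    if count < 1:
        return record, []
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    mean_isi_ms = 1000.0 / spec.rate
    # at multiplier m the epoch's mean ISI is mean/m
    epoch_len = max(3, int(round(duration_s * 1000.0 / (mean_isi_ms / mult))))
    starts = _draw_disjoint_starts(record.n_isis, count, epoch_len, rng)
    isis = record.isis.copy()
    spans = []
    for s in starts:
        isis[s : s + epoch_len] = isis[s : s + epoch_len] / mult
        spans.append((s, s + epoch_len))
    return replace(record, isis=isis, spike_times=None), spans


def generate(
    spec: GeneratorSpec, unit_id: str = "synthetic"
) -> tuple[SpikeRecord, dict]:
    """Full generation: renewal background, motifs, burst epochs.

    Returns the record and a ground-truth dict with planted occurrence
    starts and burst epoch spans.
    """
    rng = np.random.default_rng(spec.seed)
    rec = gen_renewal(spec, rng, unit_id=unit_id)
    rec, burst_spans = apply_burst_epochs(rec, spec, rng)
    rec, motif_starts = plant_motifs(rec, spec, rng)
    truth = {
        "motif_starts": motif_starts,
        "motif_length": 0 if spec.motif is None else len(spec.motif),
        "burst_epochs": burst_spans,
    }
    return rec, truth


#: Median firing rate (spikes/s) and ISI CV of each recorded population,
#: used as the default marginal statistics of the six synthetic groups.
GROUP_PRESETS: dict[tuple[str, str], tuple[float, float]] = {
    ("GPe", "normal"): (66.6, 1.13),
    ("GPe", "MPTP"): (45.7, 1.19),
    ("STN", "normal"): (22.9, 1.46),
    ("STN", "MPTP"): (36.8, 1.32),
    ("GPi", "normal"): (74.4, 0.91),
    ("GPi", "MPTP"): (75.3, 1.0),
}


@dataclass
class PopulationSpec:
    """Recipe for a multi-group synthetic dataset.

    ``motif_density`` maps a group to the number of planted occurrences of
    a group-specific 3-ISI motif per cell (0 = background only).
    """

    n_cells: int = 10
    n_isis: int = 5000
    groups: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(GROUP_PRESETS)
    )
    motif_density: dict[tuple[str, str], int] = field(default_factory=dict)
    motif_jitter: float = 0.004
    seed: int = 0


def gen_population(
    pop: PopulationSpec, out_dir: str | Path | None = None
) -> tuple[Manifest, list[SpikeRecord], dict]:
    """Generate the six structure-state groups; optionally write to disk.

    Per-cell rate and CV are drawn log-normally around the group medians
    (sigma 0.15), so group medians concentrate near their targets while
    cells differ. Writes ISI text files, a CSV manifest and a ground-truth
    JSON when ``out_dir`` is given.
    """
    master = np.random.SeedSequence(pop.seed)
    children = master.spawn(len(pop.groups) * pop.n_cells)
    records: list[SpikeRecord] = []
    rows: list[ManifestRow] = []
    truth: dict[str, dict] = {}
    k = 0
    for (structure, state), (rate, cv) in pop.groups.items():
        n_motifs = pop.motif_density.get((structure, state), 0)
        for c in range(pop.n_cells):
            rng = np.random.default_rng(children[k])
            k += 1
            cell_rate = float(rate * np.exp(rng.normal(0.0, 0.15)))
            cell_cv = float(cv * np.exp(rng.normal(0.0, 0.15)))
            uid = f"{structure}_{state}_{c:03d}"
            motif = None
            if n_motifs > 0:
                # group-typical short motif, scaled to the cell's mean ISI
                mean_isi = 1000.0 / cell_rate
                base = rng.uniform(0.3, 0.7, size=3) * mean_isi
                motif = tuple(float(v) for v in base)
            spec = GeneratorSpec(
                n_isis=pop.n_isis,
                rate=cell_rate,
                cv=cell_cv,
                motif=motif,
                n_motif_occurrences=n_motifs,
                motif_jitter=pop.motif_jitter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec, cell_truth = generate(spec, unit_id=uid)
            rec = replace(rec, structure=structure, state=state)
            records.append(rec)
            rows.append(
                ManifestRow(
                    path=f"{uid}.txt", unit_id=uid, structure=structure, state=state
                )
            )
            truth[uid] = cell_truth
    manifest = Manifest(rows=rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(records, rows):
            write_record(rec, out / row.path)
        write_manifest(manifest, out / "manifest.csv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return manifest, records, truth
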