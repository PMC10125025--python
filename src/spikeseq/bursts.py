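"""Poisson-surprise burst detection and burst/sequence overlap analyses.

The surprise statistic of a burst of ``n`` spikes spanning ``T`` seconds in
a train with mean rate ``r`` is ``S = -ln P(X >= n)`` for Poisson ``X`` with
mean ``r*T``: the negative log probability that a rate-matched Poisson
process packs at least as many spikes into the same span. Bursts are
accepted at ``S >= 3`` (chance < e^-3 ~ 5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SpikeRecord, basic_stats

#: Study cutoff for the surprise statistic.
DEFAULT_SURPRISE_CUTOFF = 3.0


def poisson_surprise(n: int, T: float, r: float) -> float:
    """Surprise ``-ln P(X >= n)``, X ~ Poisson(r*T).

    Evaluated in log space so that deep right tails (surprise of several
    hundred) keep full relative precision instead of underflowing.

    Parameters
    ----------
    n : int
        Spike count in the burst (>= 1).
    T : float
        Burst span in seconds, first to last spike (> 0).
    r : float
        Mean firing rate, spikes/s.
    """
    if T <= 0:
        raise ValueError("burst span T must be > 0")
    if n < 1:
        raise ValueError("spike count n must be >= 1")
    lam = r * T
    if lam == 0:
        return float("inf")
    if n - 1 >= lam:
        # small right tail: leading log-term times a convergent series
        log_lead = n * math.log(lam) - lam - math.lgamma(n + 1)
        s, t, k = 1.0, 1.0, n + 1
        while True:
            t *= lam / k
            s += t
            if t < 1e-18 * s:
                break
            k += 1
        return -(log_lead + math.log(s))
    # bulk/left side: P(X >= n) = 1 - P(X <= n-1); the CDF term is < ~0.5
    # here, so the complement keeps relative precision even for tiny S
    q = 0.0
    for k in range(n):
        q += math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))
    return -math.log1p(-q)


@dataclass
class Burst:
    first_spike: int
    last_spike: int
    surprise: float

    @property
    def n_spikes(self) -> int:
        return self.last_spike - self.first_spike + 1


@dataclass
class BurstSet:
    bursts: list[Burst]
    burst_isi_mask: np.ndarray

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def prop_isis_in_bursts(self) -> float:
        if self.burst_isi_mask.size == 0:
            return float("nan")
        return float(np.mean(self.burst_isi_mask))

    def to_frame(self, isis: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for b in self.bursts:
            row = {
                "first_spike": b.first_spike,
                "last_spike": b.last_spike,
                "n_spikes": b.n_spikes,
                "surprise": b.surprise,
            }
            if isis is not None:
                row["duration_ms"] = float(
                    np.sum(isis[b.first_spike : b.last_spike])
                )
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["first_spike", "last_spike", "n_spikes", "duration_ms", "surprise"]
            if isis is not None
            else ["first_spike", "last_spike", "n_spikes", "surprise"],
        )


def _span_surprise(isis: np.ndarray, a: int, b: int, r: float) -> float:
    """Surprise of the spike span [a, b] (spike indices into n_isis+1 spikes)."""
    T = float(np.sum(isis[a:b])) / 1000.0
    return poisson_surprise(b - a + 1, T, r)


def detect_bursts(
    record: SpikeRecord | np.ndarray,
    cutoff: float = DEFAULT_SURPRISE_CUTOFF,
    rate: float | None = None,
) -> BurstSet:
    """Surprise-based burst detection.

    Candidate bursts are seeded at runs of at least three consecutive ISIs
    shorter than half the mean ISI, extended spike-by-spike at the end
    while the surprise increases, then trimmed at the front likewise.
    Candidates with maximal surprise >= ``cutoff`` are retained, resolving
    overlaps in favour of the higher surprise.
    """
    if isinstance(record, SpikeRecord):
        isis = record.isis
        if rate is None:
            _, _, rate, _ = basic_stats(record)
    else:
        isis = np.asarray(record, dtype=float)
        if rate is None:
            rate = (isis.size + 1) / (float(np.sum(isis)) / 1000.0)
    n_isis = isis.size
    if n_isis < 3:
        return BurstSet(bursts=[], burst_isi_mask=np.zeros(n_isis, dtype=bool))
    mean_isi = float(np.mean(isis))
    short = isis < mean_isi / 2.0

    # maximal runs of short ISIs, length >= 3
    candidates: list[Burst] = []
    k = 0
    while k < n_isis:
        if not short[k]:
            k += 1
            continue
        run_start = k
        while k < n_isis and short[k]:
            k += 1
        run_end = k - 1  # inclusive ISI index
        if run_end - run_start + 1 < 3:
            continue
        a, b = run_start, run_end + 1  # spike indices spanning the run
        s = _span_surprise(isis, a, b, rate)
        # extend the end while surprise increases
        while b + 1 <= n_isis:
            s_next = _span_surprise(isis, a, b + 1, rate)
            if s_next > s:
                b += 1
                s = s_next
            else:
                break
        # trim leading spikes while that increases surprise (keep >= 3 spikes)
        while b - a + 1 > 3:
            s_next = _span_surprise(isis, a + 1, b, rate)
            if s_next > s:
                a += 1
                s = s_next
            else:
                break
        if s >= cutoff:
            candidates.append(Burst(first_spike=a, last_spike=b, surprise=s))

    # resolve overlapping candidates in favour of higher surprise
    retained: list[Burst] = []
    used = np.zeros(n_isis + 1, dtype=bool)
    for b in sorted(candidates, key=lambda x: (-x.surprise, x.first_spike)):
        if used[b.first_spike : b.last_spike + 1].any():
            continue
        used[b.first_spike : b.last_spike + 1] = True
        retained.append(b)
    retained.sort(key=lambda x: x.first_spike)

    mask = np.zeros(n_isis, dtype=bool)
    for b in retained:
        mask[b.first_spike : b.last_spike] = True
    return BurstSet(bursts=retained, burst_isi_mask=mask)


def overlap_metrics(
    seq_mask: np.ndarray, burst_mask: np.ndarray
) -> tuple[float, float]:
    """(fraction of sequence ISIs in bursts, fraction of burst ISIs in sequences).

    Either fraction is ``nan`` when its denominator is empty.
    """
    seq_mask = np.asarray(seq_mask, dtype=bool)
    burst_mask = np.asarray(burst_mask, dtype=bool)
    if seq_mask.shape != burst_mask.shape:
        raise ValueError("masks must have identical shape")
    both = float(np.sum(seq_mask & burst_mask))
    n_seq = float(np.sum(seq_mask))
    n_burst = float(np.sum(burst_mask))
    frac_seq_in_burst = both / n_seq if n_seq else float("nan")
    frac_burst_in_seq = both / n_burst if n_burst else float("nan")
    return frac_seq_in_burst, frac_burst_in_seq


def rate_and_burst_regressions(
    summaries: pd.DataFrame,
    y: str = "prop_isis_in_seq",
    predictors: tuple[str, ...] = ("firing_rate", "prop_isis_in_bursts"),
) -> pd.DataFrame:
    """Per structure-state group OLS of sequence participation on rate/bursts.

    Returns one row per group x predictor with slope, intercept, r^2 and
    the slope's two-sided p-value; groups with fewer than three cells are
    flagged degenerate (p is nan).
    """
    rows = []
    for (structure, state), grp in summaries.groupby(["structure", "state"]):
        for x in predictors:
            sub = grp[[x, y]].dropna()
            n = len(sub)
            if n < 3 or sub[x].nunique() < 2:
                rows.append(
                    {
                        "structure": structure,
                        "state": state,
                        "predictor": x,
                        "n": n,
                        "slope": float("nan"),
                        "intercept": float("nan"),
                        "r2": float("nan"),
                        "p": float("nan"),
                        "degenerate": True,
                    }
                )
                continue
            res = stats.linregress(sub[x].to_numpy(), sub[y].to_numpy())
            rows.append(
                {
                    "structure": structure,
                    "state": state,
                    "predictor": x,
                    "n": n,
                    "slope": float(res.slope),
                    "intercept": float(res.intercept),
                    "r2": float(res.rvalue) ** 2,
                    "p": float(res.pvalue),
                    "degenerate": False,
                }
            )
    return pd.DataFrame(rows)
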