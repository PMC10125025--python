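"""Naive O(N^2 * L) reference implementation of sequence detection.

Independent oracle for the optimized detector: plain Python lists, explicit
loops, quadratic containment and overlap checks. Implements the same
documented semantics:

* candidates are left-maximal anchor pairs (i, j) with forward-maximal
  matching runs of length >= min_length, matched element-wise against the
  template (the earlier occurrence);
* a candidate pair is suppressed when an existing family of length >= its
  run length already lists both anchors as occurrence starts;
* one family per (template, distinct run length), occurrences disjoint
  greedily left-to-right, at least two occurrences;
* longest-first retention (ties: more occurrences, then smaller template
  start): occurrences sharing any ISI index with an already retained
  occurrence are discarded (this covers full containment too); families
  keep >= 2 occurrences or are removed and claim nothing.
"""

from __future__ import annotations


def naive_run_length(isis, i, j, tol):
    n = len(isis)
    L = 0
    while j + L < n and abs(isis[j + L] - isis[i + L]) <= tol * isis[i + L]:
        L += 1
    return L


def naive_candidates(isis, tol, min_len=2):
    n = len(isis)
    cand = []
    for i in range(n - 1):
        for j in range(i + 1, n - min_len + 1):
            if i > 0 and abs(isis[j - 1] - isis[i - 1]) <= tol * isis[i - 1]:
                continue
            L = naive_run_length(isis, i, j, tol)
            if L >= min_len:
                cand.append((i, j, L))
    return cand


def naive_families(isis, tol, min_len=2):
    cand = naive_candidates(isis, tol, min_len)
    templates = sorted({i for i, _, _ in cand})
    families = []  # (template_start, length, [occ starts])
    for i in templates:
        pairs = []
        for i2, j, L in cand:
            if i2 != i:
                continue
            suppressed = False
            for ts, fl, occ in families:
                if fl >= L and i in occ and j in occ:
                    suppressed = True
                    break
            if not suppressed:
                pairs.append((j, L))
        if not pairs:
            continue
        prev = None
        for L in sorted({L for _, L in pairs}, reverse=True):
            occ = [i] + [j for j, Lj in pairs if Lj >= L]
            kept = []
            last_end = -1
            for s in occ:
                if s >= last_end:
                    kept.append(s)
                    last_end = s + L
            if len(kept) < 2 or kept == prev:
                continue
            prev = kept
            families.append((i, L, kept))
    return families


def naive_prune_contained(families):
    out = []
    for ts, L, occ in families:
        kept = []
        for s in occ:
            contained = False
            for ts2, L2, occ2 in families:
                if L2 <= L:
                    continue
                for t in occ2:
                    if t <= s and s + L <= t + L2:
                        contained = True
                        break
                if contained:
                    break
            if not contained:
                kept.append(s)
        if len(kept) >= 2:
            out.append((ts, L, kept))
    return out


def naive_resolve_overlaps(families, n_isis):
    order = sorted(families, key=lambda f: (-f[1], -len(f[2]), f[0]))
    used = set()
    retained = []
    for ts, L, occ in order:
        kept = [s for s in occ if not any(k in used for k in range(s, s + L))]
        if len(kept) < 2:
            continue
        for s in kept:
            used.update(range(s, s + L))
        retained.append((ts, L, kept))
    mask = [k in used for k in range(n_isis)]
    return retained, mask


def naive_detect(isis, tol, min_len=2):
    """Full naive pipeline; returns (families, mask)."""
    isis = list(map(float, isis))
    fams = naive_families(isis, tol, min_len)
    return naive_resolve_overlaps(fams, len(isis))
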