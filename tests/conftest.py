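"""Shared fixtures and independent reference implementations (oracles).

The oracles here deliberately use brute force — per-base bit masks,
exhaustive window enumeration, step-by-step walks — so they share no code
with the package internals they check.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from vlincscan import GeneModel, ParameterSet, ProbeMap, RatioTrack, TranscriptDomain
from vlincscan.types import ACTIVATED, REPRESSED


@pytest.fixture(autouse=True)
def _quiet_refinement_warnings():
    logging.getLogger("vlincscan.segmentation").setLevel(logging.ERROR)
    yield


def make_track(values, chrom="chr1", strand="+", spacing=25, probe_length=25):
    values = np.asarray(values, dtype=float)
    pmap = ProbeMap(
        chrom=chrom,
        strand=strand,
        positions=np.arange(len(values), dtype=np.int64) * spacing,
        probe_length=probe_length,
    )
    return RatioTrack(probe_map=pmap, values=values)


def make_domain(chrom, strand, start, end, direction, mean_ratio=None, spacing=25):
    """A TranscriptDomain for classification tests, where only the genomic
    span, strand and direction matter."""
    n = max(2, (end - start) // spacing)
    if mean_ratio is None:
        mean_ratio = 0.5 if direction == ACTIVATED else -0.5
    return TranscriptDomain(
        chrom=chrom,
        strand=strand,
        first_probe=0,
        last_probe=n - 1,
        start=start,
        end=end,
        direction=direction,
        mean_ratio=mean_ratio,
        n_probes=n,
    )


# ---------------------------------------------------------------- oracles


def seed_oracle(values, params: ParameterSet = ParameterSet()):
    """Exhaustive window enumeration for seed detection.

    Returns a sorted list of (first_probe, last_probe, direction) tuples,
    applying the same credibility filter as the caller (a run whose mean
    contradicts its direction is not a seed).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    w, k, thr = params.seed_window, params.seed_min_hits, params.seed_threshold
    out = []
    for direction, hit in (
        (ACTIVATED, values > thr),
        (REPRESSED, values < -thr),
    ):
        qualifying = [s for s in range(n - w + 1) if sum(hit[s : s + w]) >= k]
        runs = []
        for s in qualifying:
            if runs and s == runs[-1][-1] + 1:
                runs[-1].append(s)
            else:
                runs.append([s])
        for run in runs:
            first, last = run[0], run[-1] + w - 1
            mean = values[first : last + 1].mean()
            if (direction == ACTIVATED and mean < 0) or (direction == REPRESSED and mean > 0):
                continue
            out.append((first, last, direction))
    return sorted(out)


def extend_oracle(first, last, direction, values, params: ParameterSet = ParameterSet()):
    """Step-by-step expansion walk, recomputing each outward window mean naively."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    w = params.extend_window
    sign = 1 if direction == ACTIVATED else -1
    while first > 0:
        window = values[max(0, first - w) : first]
        if sign * window.mean() <= 0:
            break
        first -= 1
    while last < n - 1:
        window = values[last + 1 : min(n, last + 1 + w)]
        if sign * window.mean() <= 0:
            break
        last += 1
    return first, last


def refine_oracle(first, last, direction, values, params: ParameterSet = ParameterSet()):
    """Step-by-step boundary refinement with the frozen half-average rule.

    Returns (first, last) or None if the domain collapses below 2 probes.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    flank = params.refine_flank
    sign = 1 if direction == ACTIVATED else -1
    half = params.refine_factor * values[first : last + 1].mean()

    def decide(b, outward):
        if outward == -1:
            lo, hi = b - flank, b + flank
        else:
            lo, hi = b - flank + 1, b + flank + 1
        window = values[max(0, lo) : min(n, hi)]
        return sign * window.mean() > sign * half

    def side(b, outward, inner_limit):
        prev = None
        while True:
            decision = decide(b, outward)
            if prev is not None and decision != prev:
                return b
            nxt = b + (outward if decision else -outward)
            if nxt < 0 or nxt >= n:
                return b
            if not decision:
                if outward == -1 and nxt > inner_limit:
                    return None
                if outward == 1 and nxt < inner_limit:
                    return None
            b = nxt
            prev = decision

    new_first = side(first, -1, last - 1)
    if new_first is None:
        return None
    new_last = side(last, +1, first + 1)
    if new_last is None or new_last - new_first + 1 < 2:
        return None
    return new_first, new_last


def coverage_mask(intervals, length):
    """Per-base boolean mask over [0, length) covered by any interval."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        s, e = max(0, s), max(0, min(length, e))
        if e > s:
            mask[s:e] = True
    return mask


def unannotated_span_oracle(domain, genes):
    """Per-base mask count of domain bp not covered by same-strand genes."""
    span = domain.end - domain.start
    mask = coverage_mask(
        [
            (g.start - domain.start, g.end - domain.start)
            for g in genes
            if g.chrom == domain.chrom and g.strand == domain.strand
        ],
        span,
    )
    return int(span - mask.sum())


def interval_jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
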