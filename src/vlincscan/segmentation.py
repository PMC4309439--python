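"""Two-step domain calling on probe-level log2 ratio tracks.

Step 1 (per replicate): seed detection with a 12-probe sliding window
(>= 10 probes beyond +/-0.35), outward expansion while a 50-probe window
beyond the edge keeps the seed's sign, and merging of overlapping
same-direction domains.

Step 2 (across replicates): domains found in only one replicate are
eliminated; boundaries are then refined on a virtual track (the probe-wise
average of the replicates) using a 30-probe window against half the
domain's average, and overlapping domains are merged a final time.

Activation and repression are detected in fully independent passes.  All
windows are counted in probes; windows truncated by the chromosome end are
evaluated on the probes available, except the seed window, which requires
its full width.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import numpy as np

from .types import (
    ACTIVATED,
    DIRECTIONS,
    REPRESSED,
    ParameterSet,
    ProbeMap,
    RatioTrack,
    TranscriptDomain,
    ValidationError,
)

logger = logging.getLogger(__name__)


def _runs_of_true(mask: np.ndarray):
    """Yield (start, stop) half-open index ranges of maximal True runs."""
    if mask.size == 0:
        return
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for i in range(0, edges.size, 2):
        yield int(edges[i]), int(edges[i + 1])


def detect_seed_domains(track: RatioTrack, params: ParameterSet = ParameterSet()) -> List[TranscriptDomain]:
    """Find seed domains with the sliding-window hit-count rule.

    For each direction independently, a window of ``seed_window`` consecutive
    probes qualifies when at least ``seed_min_hits`` of its probes lie
    strictly beyond the signed threshold.  A seed is the union of probes
    covered by a maximal run of consecutive qualifying window starts.
    Values exactly at the threshold do not count as hits.
    """
    n = track.n_probes
    w = params.seed_window
    if n < w:
        return []
    seeds: List[TranscriptDomain] = []
    for direction in DIRECTIONS:
        if direction == ACTIVATED:
            hits = track.values > params.seed_threshold
        else:
            hits = track.values < -params.seed_threshold
        csum = np.concatenate(([0], np.cumsum(hits, dtype=np.int64)))
        counts = csum[w:] - csum[:-w]  # hit count in window starting at each index
        qualifying = counts >= params.seed_min_hits
        for run_start, run_stop in _runs_of_true(qualifying):
            first = run_start
            last = run_stop - 1 + w - 1  # last probe of the last qualifying window
            seed = TranscriptDomain.try_from_probes(
                track.probe_map, first, last, direction, track.values
            )
            if seed is None:  # extreme outliers can flip the run mean's sign
                logger.debug("seed %d-%d dropped: mean contradicts %s", first, last, direction)
                continue
            seeds.append(seed)
    seeds.sort(key=lambda d: (d.start, d.direction))
    return seeds


def extend_domain(
    domain: TranscriptDomain, track: RatioTrack, params: ParameterSet = ParameterSet()
) -> TranscriptDomain:
    """Expand a domain while the mean of the probes just beyond its edge
    keeps the domain's sign.

    On each side the ``extend_window`` probes immediately outside the current
    edge are averaged (fewer near the chromosome end); a positive mean
    (activated) or negative mean (repressed) advances the edge one probe.
    """
    n = track.n_probes
    if domain.first_probe < 0 or domain.last_probe >= n:
        raise ValidationError("domain lies outside the track")
    vals = track.values
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    w = params.extend_window
    want_positive = domain.direction == ACTIVATED

    def window_ok(lo: int, hi: int) -> bool:
        # mean over probe indices [lo, hi); caller guarantees hi > lo
        mean = (csum[hi] - csum[lo]) / (hi - lo)
        return mean > 0 if want_positive else mean < 0

    first = domain.first_probe
    while first > 0:
        lo = max(0, first - w)
        if not window_ok(lo, first):
            break
        first -= 1
    last = domain.last_probe
    while last < n - 1:
        hi = min(n, last + 1 + w)
        if not window_ok(last + 1, hi):
            break
        last += 1
    if first == domain.first_probe and last == domain.last_probe:
        return domain
    out = TranscriptDomain.try_from_probes(track.probe_map, first, last, domain.direction, vals)
    if out is None:
        raise ValidationError("extension produced a run whose mean contradicts its direction")
    return out


class _Extender:
    """Vectorized equivalent of :func:`extend_domain` for many seeds on one track.

    The probe-by-probe walk stops at the first outward window whose mean
    loses the seed's sign; those failure positions depend only on the track,
    so they are precomputed once per (direction, side) and each seed's final
    edge is found by binary search.  Results are identical to the walk.
    """

    def __init__(self, track: RatioTrack, params: ParameterSet):
        self.track = track
        n = track.n_probes
        w = params.extend_window
        csum = np.concatenate(([0.0], np.cumsum(track.values)))
        # right side: window over [e+1, min(n, e+1+w)) for edge e in [0, n-1)
        e = np.arange(0, n - 1) if n > 1 else np.arange(0)
        hi = np.minimum(n, e + 1 + w)
        right_mean = (csum[hi] - csum[e + 1]) / (hi - e - 1)
        # left side: window over [max(0, f-w), f) for edge f in [1, n)
        f = np.arange(1, n) if n > 1 else np.arange(0)
        lo = np.maximum(0, f - w)
        left_mean = (csum[f] - csum[lo]) / (f - lo)
        self._fail_right = {
            ACTIVATED: np.flatnonzero(~(right_mean > 0)),
            REPRESSED: np.flatnonzero(~(right_mean < 0)),
        }
        # indices into f-space are f-1; store actual f values of failures
        self._fail_left = {
            ACTIVATED: np.flatnonzero(~(left_mean > 0)) + 1,
            REPRESSED: np.flatnonzero(~(left_mean < 0)) + 1,
        }

    def extend(self, domain: TranscriptDomain) -> TranscriptDomain:
        n = self.track.n_probes
        fail_r = self._fail_right[domain.direction]
        fail_l = self._fail_left[domain.direction]
        # final right edge = first failing edge at or beyond the current one
        i = np.searchsorted(fail_r, domain.last_probe, side="left")
        last = int(fail_r[i]) if i < fail_r.size else n - 1
        # final left edge = last failing edge at or before the current one
        j = np.searchsorted(fail_l, domain.first_probe, side="right") - 1
        first = int(fail_l[j]) if j >= 0 else 0
        if first == domain.first_probe and last == domain.last_probe:
            return domain
        return TranscriptDomain.try_from_probes(
            self.track.probe_map, first, last, domain.direction, self.track.values
        )


def merge_domains(
    domains: Sequence[TranscriptDomain], track: RatioTrack
) -> List[TranscriptDomain]:
    """Merge same-direction domains whose probe ranges overlap or touch.

    Opposite-direction overlaps are left intact.  Mean ratios of merged
    domains are recomputed from the track over the union of probes, so the
    operation is idempotent and order-independent.
    """
    if not domains:
        return []
    chroms = {d.chrom for d in domains}
    strands = {d.strand for d in domains}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValidationError("merge_domains requires a single (chrom, strand)")
    merged: List[TranscriptDomain] = []
    for direction in DIRECTIONS:
        group = sorted(
            (d for d in domains if d.direction == direction), key=lambda d: d.first_probe
        )
        if not group:
            continue
        def emit(first: int, last: int) -> None:
            dom = TranscriptDomain.try_from_probes(
                track.probe_map, first, last, direction, track.values
            )
            if dom is None:
                logger.debug("merged run %d-%d dropped: mean contradicts %s", first, last, direction)
            else:
                merged.append(dom)

        cur_first, cur_last = group[0].first_probe, group[0].last_probe
        for d in group[1:]:
            if d.first_probe <= cur_last + 1:  # overlapping or touching
                cur_last = max(cur_last, d.last_probe)
            else:
                emit(cur_first, cur_last)
                cur_first, cur_last = d.first_probe, d.last_probe
        emit(cur_first, cur_last)
    merged.sort(key=lambda d: (d.start, d.direction))
    return merged


def make_virtual_track(tracks: Sequence[RatioTrack]) -> RatioTrack:
    """Probe-wise arithmetic mean of replicate tracks (the virtual experiment)."""
    if len(tracks) < 2:
        raise ValidationError("a virtual track needs at least 2 replicates")
    ref = tracks[0].probe_map
    for t in tracks[1:]:
        if not ref.same_grid(t.probe_map):
            raise ValidationError("replicate tracks use different probe maps")
    mean = np.mean([t.values for t in tracks], axis=0)
    return RatioTrack(probe_map=ref, values=mean)


def intersect_replicates(
    domains_a: Sequence[TranscriptDomain], domains_b: Sequence[TranscriptDomain]
) -> List[TranscriptDomain]:
    """Keep each reference-replicate domain that shares >= 1 probe with a
    same-direction domain of the other replicate.

    Retained domains keep the reference replicate's coordinates; their
    boundaries are re-derived later on the virtual track, which limits the
    asymmetry of using one replicate as reference.
    """
    kept = []
    by_dir = {d: [b for b in domains_b if b.direction == d] for d in DIRECTIONS}
    for a in domains_a:
        if any(a.probe_overlap(b) for b in by_dir[a.direction]):
            kept.append(a)
    return kept


def refine_boundaries(
    domain: TranscriptDomain, virtual: RatioTrack, params: ParameterSet = ParameterSet()
) -> Optional[TranscriptDomain]:
    """Refine both boundaries on the virtual track with the half-average rule.

    The domain average is computed once on entry and held fixed.  For each
    side independently, a ``2 * refine_flank``-probe window centered on the
    boundary probe is averaged; if it beats ``refine_factor`` times the
    domain average the boundary moves outward one probe, otherwise inward
    (criterion mirrored for repression).  A side stops at the first reversal
    of its expand/reduce decision, or at the chromosome end.  Returns None
    if the refined domain would shrink below 2 probes.
    """
    n = virtual.n_probes
    vals = virtual.values
    member = vals[domain.first_probe : domain.last_probe + 1]
    domain_avg = float(member.mean())
    want_positive = domain.direction == ACTIVATED
    if domain_avg == 0 or (domain_avg > 0) != want_positive:
        raise ValidationError(
            "domain mean on the virtual track is zero or inconsistent with its direction"
        )
    half = params.refine_factor * domain_avg
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    flank = params.refine_flank

    def window_mean(b: int, outward_step: int) -> float:
        # 2*flank probes split evenly: flank outside the boundary, flank
        # inside (including the boundary probe); mirrored between sides so
        # both edges behave identically on a crisp domain.
        if outward_step == -1:
            lo, hi = b - flank, b + flank
        else:
            lo, hi = b - flank + 1, b + flank + 1
        lo, hi = max(0, lo), min(n, hi)
        return (csum[hi] - csum[lo]) / (hi - lo)

    def expand_decision(b: int, outward_step: int) -> bool:
        m = window_mean(b, outward_step)
        return m > half if want_positive else m < half

    def refine_side(b: int, outward_step: int, inner_limit: int) -> Optional[int]:
        # outward_step: -1 for the left boundary, +1 for the right.
        prev = None
        while True:
            decision = expand_decision(b, outward_step)
            if prev is not None and decision != prev:
                return b
            nxt = b + (outward_step if decision else -outward_step)
            if nxt < 0 or nxt >= n:
                return b  # chromosome end
            if not decision:
                # reducing: stop short of eating the whole domain
                if outward_step == -1 and nxt > inner_limit:
                    return None
                if outward_step == 1 and nxt < inner_limit:
                    return None
            b = nxt
            prev = decision

    new_first = refine_side(domain.first_probe, -1, domain.last_probe - 1)
    if new_first is None:
        logger.warning("domain %s:%d-%d discarded during refinement", domain.chrom, domain.start, domain.end)
        return None
    new_last = refine_side(domain.last_probe, +1, domain.first_probe + 1)
    if new_last is None or new_last - new_first + 1 < 2:
        logger.warning("domain %s:%d-%d discarded during refinement", domain.chrom, domain.start, domain.end)
        return None
    return TranscriptDomain.from_probes(virtual.probe_map, new_first, new_last, domain.direction, vals)


def run_segmentation(
    tracks: Sequence[RatioTrack], params: ParameterSet = ParameterSet()
) -> List[TranscriptDomain]:
    """Full two-step domain calling over >= 2 replicate tracks.

    Per replicate: seed, extend, merge.  Then intersection (replicate 1 as
    reference, against every other replicate), boundary refinement on the
    virtual track, and a final merge.  Deterministic.
    """
    if len(tracks) < 2:
        raise ValidationError("segmentation requires at least 2 replicate tracks")
    virtual = make_virtual_track(tracks)  # also validates matching probe maps
    per_replicate = []
    for t in tracks:
        seeds = detect_seed_domains(t, params)
        if seeds:
            extender = _Extender(t, params)
            seeds = [e for e in (extender.extend(s) for s in seeds) if e is not None]
        per_replicate.append(merge_domains(seeds, t))
    consensus = per_replicate[0]
    for other in per_replicate[1:]:
        consensus = intersect_replicates(consensus, other)
    refined = []
    for dom in consensus:
        try:
            r = refine_boundaries(dom, virtual, params)
        except ValidationError:
            logger.warning(
                "domain %s:%d-%d dropped: virtual-track mean inconsistent with direction",
                dom.chrom, dom.start, dom.end,
            )
            continue
        if r is not None:
            refined.append(r)
    return merge_domains(refined, virtual)
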