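"""Randomization significance for called domains.

Each replicate track is independently randomized (preserving its multiset
of values), the full segmentation is re-run, and the best domain score per
direction is recorded.  Observed domains are compared against these
per-direction maxima, giving family-wise control over the track with a
single threshold.  The empirical P carries the +1 correction, so
P >= 1/(n_randomizations + 1) and is never zero.

The default scheme is an i.i.d. shuffle of probe values: it destroys the
contiguity that defines a transcribed domain, so the null asks how large a
domain could be assembled by chance from the same value distribution.  A
circular rotation is available behind ``method='rotate'``; note that
rotation relocates rather than destroys real contiguous signal, so when
genuine domains cover an appreciable fraction of the track their chance
same-direction overlaps between independently rotated replicates inflate
the null maxima and the test loses essentially all power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .segmentation import make_virtual_track, run_segmentation
from .types import (
    ACTIVATED,
    DIRECTIONS,
    REPRESSED,
    ParameterSet,
    RatioTrack,
    TranscriptDomain,
    ValidationError,
)


@dataclass(frozen=True)
class RandomizationResult:
    """Null maxima per direction and the P-values they induced."""

    n_randomizations: int
    null_scores: Dict[str, np.ndarray]
    p_values: tuple


def randomize_track(track: RatioTrack, seed: int, method: str = "shuffle") -> RatioTrack:
    """Return a null track: an i.i.d. shuffle (default) or a circular
    rotation by a uniform offset.  The multiset of values is preserved."""
    rng = np.random.default_rng(seed)
    return _randomize(track, rng, method)


def _randomize(track: RatioTrack, rng: np.random.Generator, method: str) -> RatioTrack:
    if method == "rotate":
        offset = int(rng.integers(0, track.n_probes))
        values = np.roll(track.values, offset)
    elif method == "shuffle":
        values = rng.permutation(track.values)
    else:
        raise ValidationError(f"unknown randomization method {method!r}")
    return RatioTrack(probe_map=track.probe_map, values=values)


def domain_score(domain: TranscriptDomain, virtual: RatioTrack) -> float:
    """Score = n_probes x |mean virtual value over member probes| = |probe sum|."""
    if domain.first_probe < 0 or domain.last_probe >= virtual.n_probes:
        raise ValidationError("domain lies outside the track")
    member = virtual.values[domain.first_probe : domain.last_probe + 1]
    if member.size == 0:
        raise ValidationError("empty domain")
    return float(abs(member.sum()))


def _max_scores_by_direction(domains: Sequence[TranscriptDomain], virtual: RatioTrack) -> Dict[str, float]:
    best = {d: 0.0 for d in DIRECTIONS}
    for dom in domains:
        best[dom.direction] = max(best[dom.direction], domain_score(dom, virtual))
    return best


def assign_pvalues(
    domains: Sequence[TranscriptDomain],
    tracks: Sequence[RatioTrack],
    params: ParameterSet = ParameterSet(),
    n_randomizations: int = 199,
    seed: int = 0,
    method: str = "shuffle",
) -> List[TranscriptDomain]:
    """Attach +1-corrected empirical P-values to domains.

    For each of ``n_randomizations`` rounds every replicate track is
    independently randomized, segmentation is re-run, and the maximum domain
    score per direction (0 if none called) forms the null.  A domain's
    P is (1 + #{null maxima >= its score, same direction}) /
    (1 + n_randomizations).
    """
    if n_randomizations < 1:
        raise ValidationError("n_randomizations must be >= 1")
    virtual = make_virtual_track(tracks)
    observed = [(dom, domain_score(dom, virtual)) for dom in domains]
    rng = np.random.default_rng(seed)
    null: Dict[str, List[float]] = {d: [] for d in DIRECTIONS}
    for _ in range(n_randomizations):
        rand_tracks = [_randomize(t, rng, method) for t in tracks]
        rand_domains = run_segmentation(rand_tracks, params)
        rand_virtual = make_virtual_track(rand_tracks)
        best = _max_scores_by_direction(rand_domains, rand_virtual)
        for d in DIRECTIONS:
            null[d].append(best[d])
    null_arr = {d: np.asarray(v) for d, v in null.items()}
    out = []
    for dom, score in observed:
        exceed = int(np.count_nonzero(null_arr[dom.direction] >= score))
        out.append(dom.with_p_value((1 + exceed) / (1 + n_randomizations)))
    return out


def filter_significant(domains: Sequence[TranscriptDomain], alpha: float = 0.025) -> List[TranscriptDomain]:
    """Retain domains with P strictly below alpha, preserving order."""
    for dom in domains:
        if dom.p_value is None:
            raise ValidationError("all domains must carry a p_value before filtering")
    return [d for d in domains if d.p_value < alpha]
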