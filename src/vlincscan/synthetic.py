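"""Synthetic tiling-array data with planted transcription domains.

Emulates normalized strand-specific tiling-array output: a uniform probe
grid carrying noisy log2(senescence/proliferative) ratios, with contiguous
planted domains of positive (activated) or negative (repressed) shift
observed in independent replicates.  Probes are spaced every 25 bp by
default so that the 12-probe seed window corresponds to roughly 300 bp —
the shortest transcript the calling algorithm can resolve.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .types import (
    ACTIVATED,
    REPRESSED,
    GeneModel,
    PlacementError,
    ProbeMap,
    RatioTrack,
    TruthDomain,
    TruthSet,
    ValidationError,
)

_MAX_PLACEMENT_TRIES = 1000


def generate_probe_map(
    chrom: str,
    strand: str,
    chrom_length: int,
    spacing: int = 25,
    probe_length: int = 25,
) -> ProbeMap:
    """Uniform probe grid at 0, spacing, 2*spacing, ... below chrom_length."""
    if chrom_length <= 0:
        raise ValidationError("chrom_length must be positive")
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    positions = np.arange(0, chrom_length, spacing, dtype=np.int64)
    return ProbeMap(chrom=chrom, strand=strand, positions=positions, probe_length=probe_length)


def generate_gene_catalog(
    chrom: str,
    chrom_length: int,
    n_genes: int,
    mean_length: int,
    seed: int,
) -> List[GeneModel]:
    """Place genes uniformly, forbidding same-strand overlap.

    Opposite-strand overlap is allowed — antisense configurations (a domain
    on one strand facing a gene on the other) are exactly what the
    classification step must see.  Gene lengths are exponential with the
    given mean, clipped to [200 bp, chrom_length].
    """
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    if mean_length <= 0:
        raise ValidationError("mean_length must be positive")
    if chrom_length <= 0:
        raise ValidationError("chrom_length must be positive")
    rng = np.random.default_rng(seed)
    placed: dict = {"+": [], "-": []}
    genes: List[GeneModel] = []
    for i in range(n_genes):
        for _ in range(_MAX_PLACEMENT_TRIES):
            length = int(np.clip(rng.exponential(mean_length), 200, chrom_length))
            start = int(rng.integers(0, max(1, chrom_length - length)))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            if all(end <= s or start >= e for s, e in placed[strand]):
                placed[strand].append((start, end))
                genes.append(
                    GeneModel(chrom=chrom, strand=strand, start=start, end=end, name=f"gene_{i:04d}")
                )
                break
        else:
            raise PlacementError(
                f"could not place gene {i} without same-strand overlap "
                f"after {_MAX_PLACEMENT_TRIES} tries"
            )
    genes.sort(key=lambda g: (g.start, g.end))
    return genes


def plant_truth(
    probe_map: ProbeMap,
    n_domains: int,
    length_range: Tuple[int, int],
    effect_range: Tuple[float, float],
    p_activated: float = 0.5,
    noise_sd: float = 0.2,
    n_replicates: int = 2,
    seed: int = 0,
) -> TruthSet:
    """Plant non-overlapping ground-truth domains on the probe grid.

    Each domain spans at least 12 probes (the seed window, the algorithm's
    resolution floor); direction is drawn with probability ``p_activated``
    and the effect magnitude uniformly from ``effect_range``.
    """
    if n_domains < 0:
        raise ValidationError("n_domains must be >= 0")
    lo, hi = length_range
    chrom_span = int(probe_map.positions[-1]) + probe_map.probe_length if len(probe_map) else 0
    if not (0 < lo <= hi <= chrom_span):
        raise ValidationError("length_range must lie within the chromosome")
    e_lo, e_hi = effect_range
    if not (0 < e_lo <= e_hi):
        raise ValidationError("effect magnitudes must be positive")
    if not (0 <= p_activated <= 1):
        raise ValidationError("p_activated must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    spacing = int(np.diff(probe_map.positions).min()) if len(probe_map) > 1 else probe_map.probe_length
    min_len = max(lo, 12 * spacing)
    placed: List[Tuple[int, int]] = []
    domains: List[TruthDomain] = []
    for _ in range(n_domains):
        for _ in range(_MAX_PLACEMENT_TRIES):
            length = int(rng.integers(min_len, max(min_len, hi) + 1))
            start = int(rng.integers(0, max(1, chrom_span - length)))
            end = start + length
            n_inside = int(np.searchsorted(probe_map.positions, end) - np.searchsorted(probe_map.positions, start))
            if n_inside < 12:
                continue
            if all(end <= s or start >= e for s, e in placed):
                direction = ACTIVATED if rng.random() < p_activated else REPRESSED
                magnitude = float(rng.uniform(e_lo, e_hi))
                effect = magnitude if direction == ACTIVATED else -magnitude
                placed.append((start, end))
                domains.append(
                    TruthDomain(
                        chrom=probe_map.chrom,
                        strand=probe_map.strand,
                        start=start,
                        end=end,
                        direction=direction,
                        effect=effect,
                    )
                )
                break
        else:
            raise PlacementError(
                f"could not place {n_domains} non-overlapping domains "
                f"(placed {len(domains)})"
            )
    domains.sort(key=lambda d: d.start)
    return TruthSet(domains=tuple(domains), noise_sd=noise_sd, n_replicates=n_replicates)


def truth_effect_profile(probe_map: ProbeMap, truth: TruthSet) -> np.ndarray:
    """Noise-free per-probe effect: the planted shift at covered probes, else 0."""
    profile = np.zeros(probe_map.n_probes)
    pos = probe_map.positions
    for dom in truth.domains:
        i0 = int(np.searchsorted(pos, dom.start, side="left"))
        i1 = int(np.searchsorted(pos, dom.end, side="left"))
        profile[i0:i1] = dom.effect
    return profile


def simulate_ratio_tracks(probe_map: ProbeMap, truth: TruthSet, seed: int = 0) -> List[RatioTrack]:
    """Simulate one noisy replicate track per replicate in the truth set.

    Value at probe p = planted effect of the domain containing p (0 outside
    all domains) + N(0, noise_sd), independently per probe and replicate.
    """
    profile = truth_effect_profile(probe_map, truth)
    rng = np.random.default_rng(seed)
    tracks = []
    for _ in range(truth.n_replicates):
        noise = rng.normal(0.0, truth.noise_sd, size=probe_map.n_probes) if truth.noise_sd > 0 else 0.0
        tracks.append(RatioTrack(probe_map=probe_map, values=profile + noise))
    return tracks


def standard_simulation(seed: int = 1):
    """The package's reference benchmark: one 5-Mb chromosome, 25-bp probe
    spacing, 20 planted domains of 2-100 kb with |effect| in [0.5, 0.8],
    Gaussian probe noise of sd 0.2, two replicates.

    Returns (probe_map, truth, tracks).
    """
    probe_map = generate_probe_map("chr1", "+", chrom_length=5_000_000, spacing=25)
    truth = plant_truth(
        probe_map,
        n_domains=20,
        length_range=(2_000, 100_000),
        effect_range=(0.5, 0.8),
        p_activated=0.5,
        noise_sd=0.2,
        n_replicates=2,
        seed=seed,
    )
    tracks = simulate_ratio_tracks(probe_map, truth, seed=seed + 1)
    return probe_map, truth, tracks
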