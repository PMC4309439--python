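"""Core data containers for tiling-array domain calling.

Coordinates are 0-based half-open throughout.  A transcript domain's genomic
span runs from the start of its first member probe to the start of its last
member probe plus the probe length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

ACTIVATED = "activated"
REPRESSED = "repressed"
DIRECTIONS = (ACTIVATED, REPRESSED)


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class PlacementError(RuntimeError):
    """Requested simulated features cannot be placed without overlap."""


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


def opposite(direction: str) -> str:
    if direction == ACTIVATED:
        return REPRESSED
    if direction == REPRESSED:
        return ACTIVATED
    raise ValidationError(f"unknown direction: {direction!r}")


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic start positions of array probes on one (chrom, strand).

    Parameters
    ----------
    chrom : chromosome name.
    strand : '+' or '-'.
    positions : strictly increasing probe start coordinates (bp, 0-based).
    probe_length : probe footprint in bp (default 25).
    """

    chrom: str
    strand: str
    positions: np.ndarray
    probe_length: int = 25

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.probe_length <= 0:
            raise ValidationError("probe_length must be positive")
        if pos.size and pos[0] < 0:
            raise ValidationError("probe positions must be non-negative")
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValidationError("probe positions must be strictly increasing")

    @property
    def n_probes(self) -> int:
        return int(self.positions.size)

    def __len__(self) -> int:
        return self.n_probes

    def same_grid(self, other: "ProbeMap") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.probe_length == other.probe_length
            and self.positions.size == other.positions.size
            and bool(np.array_equal(self.positions, other.positions))
        )


@dataclass(frozen=True)
class RatioTrack:
    """Per-probe log2(senescence/proliferative) ratios bound to a ProbeMap."""

    probe_map: ProbeMap
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.size != self.probe_map.n_probes:
            raise ValidationError(
                f"track has {vals.size} values for {self.probe_map.n_probes} probes"
            )
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValidationError("track values must all be finite")

    @property
    def n_probes(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene span (the RefSeq stand-in)."""

    chrom: str
    strand: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.name}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthDomain:
    """A planted transcription domain used as simulation ground truth."""

    chrom: str
    strand: str
    start: int
    end: int
    direction: str
    effect: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("truth domain start must be < end")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"bad direction {self.direction!r}")
        if self.direction == ACTIVATED and self.effect <= 0:
            raise ValidationError("activated domains must have positive effect")
        if self.direction == REPRESSED and self.effect >= 0:
            raise ValidationError("repressed domains must have negative effect")


@dataclass(frozen=True)
class TruthSet:
    """Planted domains plus the noise model used to simulate replicate tracks."""

    domains: tuple
    noise_sd: float
    n_replicates: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ParameterSet:
    """Tunable parameters of the domain-calling algorithm.

    seed_window / seed_min_hits / seed_threshold
        a seed begins where >= ``seed_min_hits`` of ``seed_window`` consecutive
        probes exceed +``seed_threshold`` (activation) or fall below
        -``seed_threshold`` (repression).
    extend_window
        probes averaged beyond the current edge during expansion; the edge
        advances while that average keeps the seed's sign.
    refine_flank
        half-width (probes) of the boundary-refinement window, so the window
        spans ``2 * refine_flank`` probes.
    refine_factor
        fraction of the (frozen) domain average the refinement window must
        beat for the boundary to move outward.
    vlinc_min_unannotated
        minimum bp of a domain not covered by same-strand annotation for it to
        qualify as a vlincRNA.
    alpha
        significance level applied to randomization P-values (strict <).
    """

    seed_window: int = 12
    seed_min_hits: int = 10
    seed_threshold: float = 0.35
    extend_window: int = 50
    refine_flank: int = 15
    refine_factor: float = 0.5
    vlinc_min_unannotated: int = 50_000
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.seed_window < 1 or self.extend_window < 1 or self.refine_flank < 1:
            raise ValidationError("all window sizes must be >= 1")
        if self.seed_min_hits > self.seed_window:
            raise ValidationError("seed_min_hits cannot exceed seed_window")
        if self.seed_threshold <= 0:
            raise ValidationError("seed_threshold must be positive")
        if not (0 < self.refine_factor < 1):
            raise ValidationError("refine_factor must lie in (0, 1)")
        if self.vlinc_min_unannotated < 0:
            raise ValidationError("vlinc_min_unannotated must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class TranscriptDomain:
    """A contiguous probe run called as activated or repressed.

    ``first_probe`` / ``last_probe`` are inclusive probe indices into the
    originating ProbeMap; ``start`` / ``end`` are the bp span
    [first probe start, last probe start + probe_length).
    """

    chrom: str
    strand: str
    first_probe: int
    last_probe: int
    start: int
    end: int
    direction: str
    mean_ratio: float
    n_probes: int
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.first_probe > self.last_probe:
            raise ValidationError("first_probe must be <= last_probe")
        if self.n_probes != self.last_probe - self.first_probe + 1:
            raise ValidationError("n_probes inconsistent with probe indices")
        if self.start >= self.end:
            raise ValidationError("domain start must be < end")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"bad direction {self.direction!r}")
        if self.direction == ACTIVATED and self.mean_ratio < 0:
            raise ValidationError("activated domain with negative mean_ratio")
        if self.direction == REPRESSED and self.mean_ratio > 0:
            raise ValidationError("repressed domain with positive mean_ratio")
        if self.p_value is not None and not (0 < self.p_value <= 1):
            raise ValidationError("p_value must lie in (0, 1]")

    @staticmethod
    def from_probes(
        probe_map: ProbeMap,
        first_probe: int,
        last_probe: int,
        direction: str,
        values: np.ndarray,
        p_value: Optional[float] = None,
    ) -> "TranscriptDomain":
        """Build a domain from inclusive probe indices and a value array."""
        if first_probe < 0 or last_probe >= probe_map.n_probes:
            raise ValidationError("probe indices outside the probe map")
        member = np.asarray(values, dtype=np.float64)[first_probe : last_probe + 1]
        return TranscriptDomain(
            chrom=probe_map.chrom,
            strand=probe_map.strand,
            first_probe=int(first_probe),
            last_probe=int(last_probe),
            start=int(probe_map.positions[first_probe]),
            end=int(probe_map.positions[last_probe]) + probe_map.probe_length,
            direction=direction,
            mean_ratio=float(member.mean()),
            n_probes=int(last_probe - first_probe + 1),
            p_value=p_value,
        )

    @staticmethod
    def try_from_probes(
        probe_map: ProbeMap,
        first_probe: int,
        last_probe: int,
        direction: str,
        values: np.ndarray,
    ) -> Optional["TranscriptDomain"]:
        """Like :meth:`from_probes`, but returns None when the probe-run mean
        contradicts the direction (a candidate that is not a credible call)."""
        member = np.asarray(values, dtype=np.float64)[first_probe : last_probe + 1]
        mean = float(member.mean())
        if (direction == ACTIVATED and mean < 0) or (direction == REPRESSED and mean > 0):
            return None
        return TranscriptDomain.from_probes(probe_map, first_probe, last_probe, direction, values)

    def with_p_value(self, p: float) -> "TranscriptDomain":
        return replace(self, p_value=float(p))

    def probe_overlap(self, other: "TranscriptDomain") -> bool:
        """True if the two domains share at least one probe index."""
        return self.first_probe <= other.last_probe and other.first_probe <= self.last_probe
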