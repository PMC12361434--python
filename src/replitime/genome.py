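"""Genome model, genomic regions and bin-grid arithmetic.

All coordinates are 0-based half-open; bin ``i`` of a grid with bin size
``b`` covers ``[i*b, (i+1)*b)``.  Each chromosome contributes
``floor(length / b)`` full bins — a trailing partial bin is dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["Region", "Genome", "make_genome"]

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class Region:
    """A chromosome interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def parse(cls, text: str, label: str | None = None) -> "Region":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        start = int(m.group(2).replace(",", ""))
        end = int(m.group(3).replace(",", ""))
        return cls(m.group(1), start, end, label=label)

    def overlaps(self, other: "Region") -> bool:
        """Any-overlap rule: >= 1 bp shared."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Genome:
    """Chromosome names and lengths with a fixed bin grid.

    Parameters
    ----------
    names : tuple of str
        Chromosome identifiers, in order.
    lengths : tuple of int
        Chromosome lengths in bp, aligned with *names*.
    bin_size : int
        Width of a grid bin in bp (default 50 kb).
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int = 50_000

    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(self.names) != len(self.lengths) or not self.names:
            raise ValueError("names and lengths must be non-empty and aligned")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.names, self.lengths):
            if length <= self.bin_size:
                raise ValueError(
                    f"chromosome {name} length {length} must exceed bin_size"
                )
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.names)}
        )

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.lengths[self._index[chrom]]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_size: int | None = None) -> int:
        b = self.bin_size if bin_size is None else bin_size
        return self.chrom_length(chrom) // b

    def validate_region(self, region: Region) -> None:
        """Raise ValueError if *region* falls off this genome."""
        if region.chrom not in self._index:
            raise ValueError(f"region chromosome {region.chrom!r} not in genome")
        if region.end > self.chrom_length(region.chrom):
            raise ValueError(
                f"region {region} exceeds chromosome length "
                f"{self.chrom_length(region.chrom)}"
            )

    # --- bin selection rules -------------------------------------------------

    def overlapping_bins(self, region: Region, bin_size: int | None = None) -> slice:
        """Indices of bins sharing >= 1 bp with *region* (any-overlap rule)."""
        self.validate_region(region)
        b = self.bin_size if bin_size is None else bin_size
        n = self.n_bins(region.chrom, b)
        lo = max(0, region.start // b)
        hi = min(n, -(-region.end // b))  # ceil division
        return slice(lo, max(lo, hi))

    def midpoint_bins(self, region: Region, bin_size: int | None = None) -> slice:
        """Indices of bins whose midpoint falls inside *region*."""
        self.validate_region(region)
        b = self.bin_size if bin_size is None else bin_size
        n = self.n_bins(region.chrom, b)
        # midpoint of bin i is (i + 0.5) * b; require start <= mid < end
        lo = max(0, -(-(2 * region.start - b) // (2 * b)))
        hi = min(n, -(-(2 * region.end - b) // (2 * b)))
        return slice(lo, max(lo, hi))


def make_genome(
    n_chrom: int,
    lengths: int | list[int] | tuple[int, ...],
    bin_size: int = 50_000,
    seed: int | None = None,
) -> Genome:
    """Build a genome of ``n_chrom`` chromosomes named chr1..chrN.

    ``lengths`` may be a single bp length applied to every chromosome or a
    per-chromosome list.  ``seed`` is accepted for interface uniformity with
    the simulation entry points and ignored: construction is deterministic.
    """
    if n_chrom <= 0:
        raise ValueError("n_chrom must be positive")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if isinstance(lengths, int):
        lengths = [lengths] * n_chrom
    lengths = tuple(int(x) for x in lengths)
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")
    for length in lengths:
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        if length < 10 * bin_size:
            raise ValueError("chromosome lengths must be >= 10 x bin_size")
    names = tuple(f"chr{i + 1}" for i in range(n_chrom))
    return Genome(names=names, lengths=lengths, bin_size=bin_size)
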