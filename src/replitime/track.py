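"""Binned genomic signal tracks with missing-value support.

A :class:`BinnedTrack` holds one float array per chromosome, aligned to a
fixed bin grid.  Missing bins are NaN.  Tracks carry a processing ``stage``
tag (counts, raw_rt, scaled, normalized, smoothed, delta, coverage) and
free-form metadata (clone, allele, replicate, fraction).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .genome import Genome, Region

__all__ = ["BinnedTrack", "STAGES"]

STAGES = (
    "counts",
    "raw_rt",
    "scaled",
    "normalized",
    "smoothed",
    "delta",
    "coverage",
)


class BinnedTrack:
    """One genomic signal on a fixed bin grid.

    Parameters
    ----------
    genome : Genome
        The genome whose chromosomes define the grid.
    data : mapping of chromosome name to 1-D float array, optional
        Values per bin; omitted chromosomes are all-NaN.  Arrays are
        converted to float64 and must match the grid length.
    stage : str
        Processing stage tag; one of :data:`STAGES`.
    bin_size : int, optional
        Grid bin width; defaults to ``genome.bin_size``.  Coverage tracks
        (e.g. nascent-transcription signal at 1 kb) use a finer grid than
        the genome's Repli-seq grid.
    meta : dict
        Free-form sample metadata (clone, allele, replicate, fraction).
    """

    def __init__(
        self,
        genome: Genome,
        data: Mapping[str, np.ndarray] | None = None,
        stage: str = "counts",
        bin_size: int | None = None,
        meta: dict | None = None,
    ) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        self.genome = genome
        self.stage = stage
        self.bin_size = genome.bin_size if bin_size is None else int(bin_size)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.meta = dict(meta or {})
        self.data: dict[str, np.ndarray] = {}
        data = data or {}
        unknown = set(data) - set(genome.names)
        if unknown:
            raise ValueError(f"data for unknown chromosomes: {sorted(unknown)}")
        for chrom in genome.names:
            n = genome.n_bins(chrom, self.bin_size)
            if chrom in data:
                arr = np.asarray(data[chrom], dtype=float)
                if arr.shape != (n,):
                    raise ValueError(
                        f"{chrom}: expected {n} bins, got shape {arr.shape}"
                    )
                self.data[chrom] = arr.copy()
            else:
                self.data[chrom] = np.full(n, np.nan)

    # --- construction helpers ------------------------------------------------

    @classmethod
    def zeros(
        cls,
        genome: Genome,
        stage: str = "counts",
        bin_size: int | None = None,
        meta: dict | None = None,
    ) -> "BinnedTrack":
        t = cls(genome, stage=stage, bin_size=bin_size, meta=meta)
        for chrom in t.data:
            t.data[chrom][:] = 0.0
        return t

    def copy(self, stage: str | None = None, meta: dict | None = None) -> "BinnedTrack":
        return BinnedTrack(
            self.genome,
            data=self.data,
            stage=self.stage if stage is None else stage,
            bin_size=self.bin_size,
            meta=dict(self.meta) if meta is None else meta,
        )

    # --- accessors -----------------------------------------------------------

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    @property
    def chroms(self) -> tuple[str, ...]:
        return self.genome.names

    def flatten(self) -> np.ndarray:
        """All values concatenated in chromosome order."""
        return np.concatenate([self.data[c] for c in self.chroms])

    def n_bins_total(self) -> int:
        return sum(arr.size for arr in self.data.values())

    def region_values(self, region: Region, rule: str = "midpoint") -> np.ndarray:
        """Values of bins selected by *region* (view, not a copy).

        ``rule`` is ``"midpoint"`` (bin midpoint inside region) or
        ``"overlap"`` (>= 1 bp overlap).
        """
        if rule == "midpoint":
            sl = self.genome.midpoint_bins(region, self.bin_size)
        elif rule == "overlap":
            sl = self.genome.overlapping_bins(region, self.bin_size)
        else:
            raise ValueError("rule must be 'midpoint' or 'overlap'")
        return self.data[region.chrom][sl]

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.genome == other.genome
            and self.bin_size == other.bin_size
        )

    def require_same_grid(self, other: "BinnedTrack") -> None:
        if not self.same_grid(other):
            raise ValueError("tracks are on different bin grids")

    def allclose(self, other: "BinnedTrack", **kw) -> bool:
        if not self.same_grid(other):
            return False
        return all(
            np.allclose(self.data[c], other.data[c], equal_nan=True, **kw)
            for c in self.chroms
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BinnedTrack(stage={self.stage!r}, bin_size={self.bin_size}, "
            f"bins={self.n_bins_total()}, meta={self.meta})"
        )


def stack_values(tracks: Iterable[BinnedTrack]) -> np.ndarray:
    """Stack flattened track values into an (n_bins, n_tracks) matrix."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks given")
    first = tracks[0]
    for t in tracks[1:]:
        first.require_same_grid(t)
    return np.column_stack([t.flatten() for t in tracks])


def unflatten_like(template: BinnedTrack, values: np.ndarray, stage: str) -> BinnedTrack:
    """Rebuild a track from a flat value vector on *template*'s grid."""
    out = template.copy(stage=stage)
    pos = 0
    for chrom in out.chroms:
        n = out.data[chrom].size
        out.data[chrom] = np.asarray(values[pos : pos + n], dtype=float).copy()
        pos += n
    if pos != values.size:
        raise ValueError("value vector does not match grid size")
    return out
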