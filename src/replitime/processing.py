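"""From binned early/late counts to smoothed replication-timing profiles.

Pipeline order, applied jointly to all samples of a run:

    log2(E/L) -> per-sample scaling -> quantile normalization -> loess

Per bin the raw signal is log2((early + pc) / (late + pc)); bins with no
reads in either fraction (hemizygous deletions, unmappable gaps) are
missing and stay missing through every stage.  Scaling standardizes each
sample genome-wide (mean 0, sd 1); quantile normalization equalizes the
value distributions across samples, rank by rank, preprocessCore-style;
loess smoothing fits tricube-weighted local linear regressions over a
fixed genomic window per chromosome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .genome import Region
from .track import BinnedTrack, stack_values, unflatten_like

__all__ = [
    "DegenerateDataError",
    "ProcessingConfig",
    "log2_el",
    "scale_track",
    "quantile_normalize",
    "loess_smooth",
    "average_tracks",
    "mask_regions",
    "run_processing",
    "process_dataset",
    "allele_profiles",
]

log = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Input carries too little usable signal for the requested operation."""


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunable pipeline parameters.

    pseudocount : added to both fractions before the log ratio (default 0;
        zero-total bins are missing regardless).
    smooth_window : loess window in bp (default 300 kb; each fit uses
        neighbors within window/2 on each side).
    """

    pseudocount: float = 0.0
    smooth_window: int = 300_000


def log2_el(
    early: BinnedTrack, late: BinnedTrack, pseudocount: float = 0.0
) -> BinnedTrack:
    """log2 ratio of early-to-late read counts per bin.

    Bins where early + late == 0 are set missing regardless of the
    pseudocount: a zero total means no sequence was observed (deletion or
    gap), not a measured ratio.
    """
    early.require_same_grid(late)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    meta = {k: v for k, v in early.meta.items() if k != "fraction"}
    out = early.copy(stage="raw_rt", meta=meta)
    for chrom in out.chroms:
        e = early.data[chrom]
        l = late.data[chrom]
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2((e + pseudocount) / (l + pseudocount))
        vals = np.where(e + l == 0, np.nan, vals)
        vals = np.where(np.isfinite(vals), vals, np.nan)
        out.data[chrom] = vals
    return out


def scale_track(track: BinnedTrack) -> BinnedTrack:
    """Standardize non-missing values genome-wide to mean 0, sample sd 1."""
    flat = track.flatten()
    finite = flat[np.isfinite(flat)]
    if finite.size < 2:
        raise DegenerateDataError("scaling needs >= 2 non-missing values")
    sd = np.std(finite, ddof=1)
    if sd == 0:
        raise DegenerateDataError("scaling undefined for a constant track")
    mean = finite.mean()
    out = track.copy(stage="scaled")
    for chrom in out.chroms:
        out.data[chrom] = (track.data[chrom] - mean) / sd
    return out


def quantile_normalize(tracks: list[BinnedTrack]) -> list[BinnedTrack]:
    """Rank-mean quantile normalization across samples.

    Computed on the intersection of bins non-missing in every track (rank
    maps require complete vectors); bins outside the intersection are
    missing in all outputs.  For each track, the value of rank r is
    replaced by the across-track mean of rank-r values; tied values
    receive the mean of their tied target values.
    """
    if not tracks:
        raise ValueError("no tracks to normalize")
    if len(tracks) == 1:
        warnings.warn("single track: quantile normalization skipped")
        return [tracks[0].copy(stage="normalized")]
    X = stack_values(tracks)  # (n_bins, n_tracks)
    common = np.all(np.isfinite(X), axis=1)
    sub = X[common]
    out_vals = np.full_like(X, np.nan)
    if sub.shape[0] >= 1:
        out_vals[common] = _rank_mean_normalize(sub)
    return [
        unflatten_like(t, out_vals[:, j], stage="normalized")
        for j, t in enumerate(tracks)
    ]


def _rank_mean_normalize(X: np.ndarray) -> np.ndarray:
    """Core rank-mean map on a complete (n, k) matrix."""
    n, k = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    target = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        ordj = X[order[:, j], j]
        # runs of tied values share the mean of their target slots
        boundaries = np.flatnonzero(np.diff(ordj) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        col = np.empty(n)
        for s, e in zip(starts, ends):
            col[order[s:e, j]] = target[s:e].mean()
        out[:, j] = col
    return out


def loess_smooth(track: BinnedTrack, window: int = 300_000) -> BinnedTrack:
    """Loess-smooth per chromosome over a fixed genomic window.

    Tricube-weighted locally linear fits (statsmodels lowess); each fitted
    point uses the neighbors within window/2 on each side, expressed as
    the equivalent fraction of the chromosome's non-missing bins.  The
    tricube support extends one bin beyond window/2 so that the bins at
    the window edge carry strictly positive weight (tricube vanishes at
    its support boundary).  Missing bins are excluded from the fits and
    remain missing.
    """
    if window < 3 * track.bin_size:
        raise ValueError("window must be >= 3 x bin_size")
    half_bins = (window // 2) // track.bin_size
    k = 2 * (half_bins + 1) + 1
    out = track.copy(stage="smoothed")
    for chrom in out.chroms:
        y = track.data[chrom]
        finite = np.isfinite(y)
        n_ok = int(finite.sum())
        if n_ok < 3:
            warnings.warn(f"{chrom}: fewer than 3 non-missing bins, left unsmoothed")
            continue
        x = np.flatnonzero(finite).astype(float)
        frac = min(1.0, max(k, 2) / n_ok)
        fitted = sm.nonparametric.lowess(
            y[finite], x, frac=frac, it=0, delta=0.0, return_sorted=False
        )
        smoothed = np.full_like(y, np.nan)
        smoothed[finite] = fitted
        out.data[chrom] = smoothed
    return out


def average_tracks(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Per-bin nan-aware mean; a bin is missing only if missing everywhere."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        first.require_same_grid(t)
        if t.stage != first.stage:
            raise ValueError("tracks must share a processing stage")
    out = first.copy()
    for chrom in out.chroms:
        stacked = np.vstack([t.data[chrom] for t in tracks])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            out.data[chrom] = np.nanmean(stacked, axis=0)
    return out


def mask_regions(track: BinnedTrack, regions: list[Region]) -> BinnedTrack:
    """Set bins overlapping any region (>= 1 bp) to missing."""
    out = track.copy()
    for region in regions:
        sl = track.genome.overlapping_bins(region, track.bin_size)
        out.data[region.chrom][sl] = np.nan
    return out


def run_processing(
    samples: dict[object, tuple[BinnedTrack, BinnedTrack]],
    config: ProcessingConfig = ProcessingConfig(),
) -> dict[object, BinnedTrack]:
    """Full pipeline over a run of samples.

    ``samples`` maps a sample key (e.g. (clone, allele, replicate)) to its
    (early, late) count tracks.  Quantile normalization is applied jointly
    over all samples of the run.
    """
    keys = list(samples)
    if not keys:
        raise ValueError("empty sample set")
    log.info("log2(E/L) for %d samples", len(keys))
    raw = [
        log2_el(samples[k][0], samples[k][1], pseudocount=config.pseudocount)
        for k in keys
    ]
    log.info("scaling")
    scaled = [scale_track(t) for t in raw]
    log.info("quantile normalization")
    normalized = quantile_normalize(scaled)
    log.info("loess smoothing (window %d bp)", config.smooth_window)
    smoothed = [loess_smooth(t, window=config.smooth_window) for t in normalized]
    return dict(zip(keys, smoothed))


def process_dataset(dataset, config: ProcessingConfig = ProcessingConfig()):
    """Process a :class:`~replitime.simulate.SimulatedDataset`.

    Returns a dict mapping (allele, replicate) to its smoothed RT track.
    """
    samples = {}
    for allele in dataset.alleles:
        for rep in dataset.replicates:
            samples[(allele, rep)] = (
                dataset.counts[(allele, rep, "early")],
                dataset.counts[(allele, rep, "late")],
            )
    return run_processing(samples, config=config)


def allele_profiles(processed: dict) -> dict[str, BinnedTrack]:
    """Replicate-averaged smoothed profile per allele."""
    by_allele: dict[str, list[BinnedTrack]] = {}
    for (allele, _rep), track in processed.items():
        by_allele.setdefault(allele, []).append(track)
    return {a: average_tracks(ts) for a, ts in by_allele.items()}
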