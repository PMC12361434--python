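"""Companion quantifications: nascent transcription, peak overlap, and
hemizygous-deletion detection from allele coverage.

Bru-seq signal is RPM-normalized 1 kb coverage averaged over gene bodies;
deletion/control expression ratios compare deletion-allele signal to the
average of all control alleles.  ChIP peak overlap is reported as the
percentage of datasets for a factor with at least one peak overlapping a
site (one peak call from one dataset per site).  Hemizygous deletions are
detected as runs of bins where one allele's coverage collapses while the
other allele remains well covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .genome import Region
from .processing import DegenerateDataError
from .track import BinnedTrack

__all__ = [
    "Gene",
    "PeakCollection",
    "rpm_normalize",
    "gene_body_signal",
    "expression_ratio",
    "domain_total_signal",
    "rt_domain_mean",
    "pearson_r",
    "peak_overlap_percent",
    "detect_hemizygous_deletions",
]


@dataclass(frozen=True)
class Gene:
    """A gene body; strand is informational."""

    name: str
    body: Region
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class PeakCollection:
    """Peak calls from one ChIP-seq dataset for one factor."""

    dataset_id: str
    factor: str
    peaks: tuple[Region, ...]


def rpm_normalize(track: BinnedTrack, library_size: float) -> BinnedTrack:
    """Reads-per-million scaling: value * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    out = track.copy()
    factor = 1e6 / library_size
    for chrom in out.chroms:
        out.data[chrom] = track.data[chrom] * factor
    return out


def gene_body_signal(
    track: BinnedTrack, genes: dict[str, Region] | list[Gene]
) -> dict[str, float]:
    """Nan-aware mean of bins whose midpoints fall inside each gene body.

    Genes whose body covers no bins are reported as NaN.
    """
    if isinstance(genes, dict):
        items = list(genes.items())
    else:
        items = [(g.name, g.body) for g in genes]
    result: dict[str, float] = {}
    for name, body in items:
        track.genome.validate_region(body)
        vals = track.region_values(body, rule="midpoint")
        finite = vals[np.isfinite(vals)]
        result[name] = float(finite.mean()) if finite.size else float("nan")
    return result


def expression_ratio(
    del_signals: dict[str, float] | list[dict[str, float]],
    con_signals: dict[str, float] | list[dict[str, float]],
) -> dict[str, float]:
    """Fraction of deletion-allele signal over the control-allele average.

    Inputs are per-gene mean signals, either one dict or a list of dicts
    (one per allele/clone); lists are averaged per gene first.  Genes with
    zero or missing control signal are reported as NaN with a warning.
    """
    del_mean = _mean_signals(del_signals)
    con_mean = _mean_signals(con_signals)
    out: dict[str, float] = {}
    for gene, d in del_mean.items():
        c = con_mean.get(gene, float("nan"))
        if not np.isfinite(c) or c <= 0:
            warnings.warn(f"gene {gene}: control signal missing or zero")
            out[gene] = float("nan")
        else:
            out[gene] = d / c
    return out


def _mean_signals(signals) -> dict[str, float]:
    if isinstance(signals, dict):
        return dict(signals)
    acc: dict[str, list[float]] = {}
    for s in signals:
        for g, v in s.items():
            acc.setdefault(g, []).append(v)
    return {
        g: float(np.nanmean(vs)) if np.any(np.isfinite(vs)) else float("nan")
        for g, vs in acc.items()
    }


def domain_total_signal(
    signals: dict[str, float], genes: dict[str, Region]
) -> float:
    """Total gene-body signal in a domain: sum of mean x body length."""
    total = 0.0
    for name, mean in signals.items():
        if name in genes and np.isfinite(mean):
            total += mean * genes[name].length
    return total


def rt_domain_mean(profile: BinnedTrack, region: Region) -> float:
    """Nan-aware mean RT over bins with midpoints inside *region*."""
    vals = profile.region_values(region, rule="midpoint")
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise DegenerateDataError(f"region {region} has no covered bins")
    return float(finite.mean())


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation with strict input validation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    return float(sps.pearsonr(x, y).statistic)


def peak_overlap_percent(
    collections: list[PeakCollection], site: Region
) -> float:
    """Percentage of datasets with >= 1 peak overlapping *site*.

    Multiple overlapping peaks within one dataset count once (one peak
    call from one dataset per site).
    """
    if not collections:
        raise ValueError("no peak datasets for this factor")
    hits = sum(
        1 for c in collections if any(p.overlaps(site) for p in c.peaks)
    )
    return 100.0 * hits / len(collections)


def detect_hemizygous_deletions(
    allele1: BinnedTrack,
    allele2: BinnedTrack,
    min_bins: int = 2,
    ratio_floor: float = 0.05,
) -> list[Region]:
    """Detect one-allele coverage dropouts (missing sequence on one allele).

    Reports maximal runs of >= ``min_bins`` consecutive bins where one
    allele's count is <= ``ratio_floor`` times the other's; a run is kept
    only if the other allele's mean coverage over the run reaches its
    genome-wide 10th percentile, so shared unmappable gaps are not
    called.  Regions are labeled with the depleted allele.
    """
    allele1.require_same_grid(allele2)
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")
    if ratio_floor < 0:
        raise ValueError("ratio_floor must be >= 0")
    labels = (
        allele1.meta.get("allele", "allele1"),
        allele2.meta.get("allele", "allele2"),
    )
    flats = (allele1.flatten(), allele2.flatten())
    if not any(np.nansum(f) > 0 for f in flats):
        raise ValueError("total coverage must be positive")
    q10 = [float(np.nanpercentile(f, 10)) for f in flats]
    regions: list[Region] = []
    for chrom in allele1.chroms:
        a = (allele1.data[chrom], allele2.data[chrom])
        for depleted, other in ((0, 1), (1, 0)):
            cond = a[depleted] <= ratio_floor * a[other]
            regions.extend(
                _runs_to_regions(
                    cond, chrom, allele1.bin_size, min_bins, labels[depleted],
                    coverage=a[other], floor=q10[other],
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _runs_to_regions(cond, chrom, bin_size, min_bins, label, coverage, floor):
    out = []
    padded = np.concatenate(([False], cond, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start < min_bins:
            continue
        # the retained allele must be adequately covered over the run,
        # otherwise this is a shared gap, not a hemizygous deletion
        if np.nanmean(coverage[start:end]) < floor:
            continue
        out.append(
            Region(chrom, int(start) * bin_size, int(end) * bin_size, label=label)
        )
    return out
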