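"""Randomization-based significance of replication-timing changes.

The delay imposed by a deletion is quantified as the area between the
deletion-allele and control-allele RT curves over a query domain (the
trapezoidal integral of the per-bin ΔRT = deletion − control, with x in
bin-index units).  Its significance is assessed against an empirical null
built by sampling size-matched regions genome-wide — excluding a
blacklist of regions with known allele-specific RT — and computing the
same signed area from the clone's own genome-wide ΔRT curve, which
captures the random fluctuation between the two alleles.

Delay is the negative direction: a delayed deletion allele replicates
later, so its log2(E/L) is lower and the signed area is negative.  The
one-sided empirical p-value uses the add-one (permutation-style)
correction.  ΔΔRT comparisons between two deletions use the same
framework on the per-bin difference of the two clones' ΔRT curves, with a
two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome, Region
from .processing import DegenerateDataError, average_tracks
from .simulate import rng_for
from .track import BinnedTrack

__all__ = [
    "SamplingInfeasibleError",
    "NullDistribution",
    "SignifResult",
    "delta_curve",
    "aggregate_wt_control",
    "area_between",
    "sample_null_regions",
    "null_area_distribution",
    "empirical_pvalue",
    "test_rt_delay",
    "test_delta_delta",
]

_STAGE_NULL = 7  # seed fan-out key for null-region sampling


class SamplingInfeasibleError(RuntimeError):
    """No valid null-region placement exists (or rejection limit hit)."""


@dataclass
class NullDistribution:
    """Signed areas of size-matched random regions."""

    areas: np.ndarray
    regions: list[Region]
    seed: int
    blacklist: tuple[Region, ...]

    @property
    def n(self) -> int:
        return int(self.areas.size)


@dataclass
class SignifResult:
    """Outcome of one randomization test."""

    delta_area: float
    pvalue: float
    n_random: int
    query: Region
    kind: str = "delay"  # or "delta_delta"
    alpha: float = 0.05
    control_mode: str = "internal"  # or "aggregate"
    seed: int = 0

    @property
    def abs_delta_area(self) -> float:
        return abs(self.delta_area)

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def delta_curve(
    del_profile: BinnedTrack, con_profile: BinnedTrack
) -> BinnedTrack:
    """Per-bin ΔRT = deletion − control; missing propagates."""
    del_profile.require_same_grid(con_profile)
    out = del_profile.copy(
        stage="delta",
        meta={
            "deletion": del_profile.meta.get("allele"),
            "control": con_profile.meta.get("allele"),
        },
    )
    for chrom in out.chroms:
        out.data[chrom] = del_profile.data[chrom] - con_profile.data[chrom]
    return out


def aggregate_wt_control(profiles: list[BinnedTrack]) -> BinnedTrack:
    """Average of all available WT-allele profiles across clones.

    Used as the control curve for clones without an internal WT allele
    (homozygous deletions).
    """
    if not profiles:
        raise ValueError("no WT profiles to aggregate")
    out = average_tracks(profiles)
    out.meta["allele"] = "aggregate_wt"
    return out


def area_between(curve: BinnedTrack, region: Region) -> float:
    """Signed trapezoidal area of a ΔRT curve over *region*.

    x is in bin-index units (one bin = one unit), over bins whose
    midpoints fall inside the region.  Missing bins at the edges are
    trimmed; missing interior bins are bridged by linear interpolation.
    A constant value c over k+1 bins integrates to c*k.
    """
    sl = curve.genome.midpoint_bins(region, curve.bin_size)
    y = curve.data[region.chrom][sl].copy()
    finite = np.isfinite(y)
    if finite.sum() < 2:
        raise DegenerateDataError(
            f"region {region} overlaps fewer than 2 non-missing bins"
        )
    first, last = np.flatnonzero(finite)[[0, -1]]
    y = y[first : last + 1]
    finite = np.isfinite(y)
    x = np.arange(y.size, dtype=float)
    if not finite.all():
        y[~finite] = np.interp(x[~finite], x[finite], y[finite])
    return float(np.trapezoid(y, x))


def sample_null_regions(
    genome: Genome,
    length: int,
    n: int,
    blacklist: tuple[Region, ...] | list[Region] = (),
    seed: int = 0,
    curve: BinnedTrack | None = None,
    max_missing_frac: float = 0.2,
    max_rejections: int = 10**6,
) -> list[Region]:
    """Sample *n* size-matched regions uniformly over valid placements.

    Start positions are uniform over all placements genome-wide
    (chromosomes weighted by their number of valid starts), sampling with
    replacement.  A placement is rejected if it overlaps the blacklist by
    >= 1 bp or — when *curve* is given — if more than ``max_missing_frac``
    of its bins are missing (or fewer than 2 are usable).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    starts_per_chrom = np.array(
        [max(0, genome.chrom_length(c) - length + 1) for c in genome.names],
        dtype=np.int64,
    )
    total = int(starts_per_chrom.sum())
    if total == 0:
        raise SamplingInfeasibleError(
            f"no chromosome admits a region of length {length}"
        )
    cum = np.cumsum(starts_per_chrom)
    rng = rng_for(seed, _STAGE_NULL)
    regions: list[Region] = []
    rejections = 0
    while len(regions) < n:
        u = int(rng.integers(total))
        ci = int(np.searchsorted(cum, u, side="right"))
        start = u - (int(cum[ci - 1]) if ci > 0 else 0)
        region = Region(genome.names[ci], start, start + length)
        if _rejected(region, blacklist, curve, max_missing_frac):
            rejections += 1
            if rejections > max_rejections:
                raise SamplingInfeasibleError(
                    "rejection limit reached while sampling null regions"
                )
            continue
        rejections = 0
        regions.append(region)
    return regions


def _rejected(
    region: Region,
    blacklist,
    curve: BinnedTrack | None,
    max_missing_frac: float,
) -> bool:
    for bl in blacklist:
        if region.overlaps(bl):
            return True
    if curve is not None:
        vals = curve.region_values(region, rule="midpoint")
        if vals.size == 0:
            return True
        finite = np.isfinite(vals)
        if finite.sum() < 2:
            return True
        if 1.0 - finite.mean() > max_missing_frac:
            return True
    return False


def null_area_distribution(
    curve: BinnedTrack, regions: list[Region], seed: int = 0,
    blacklist: tuple[Region, ...] = (),
) -> NullDistribution:
    """Signed area of the ΔRT curve over each sampled region."""
    areas = np.array([area_between(curve, r) for r in regions], dtype=float)
    return NullDistribution(
        areas=areas, regions=list(regions), seed=seed, blacklist=tuple(blacklist)
    )


def empirical_pvalue(
    observed: float,
    null: NullDistribution | np.ndarray,
    alternative: str = "delay",
) -> float:
    """Add-one empirical p-value against the null areas.

    ``alternative="delay"``: one-sided in the negative direction
    (deletion later ⇒ lower log2(E/L) ⇒ more negative area), so
    p = (1 + #{null <= observed}) / (1 + n).
    ``alternative="two-sided"``: p = (1 + #{|null| >= |observed|}) / (1 + n).
    """
    areas = null.areas if isinstance(null, NullDistribution) else np.asarray(null)
    if areas.size == 0:
        raise ValueError("empty null distribution")
    n = areas.size
    if alternative == "delay":
        count = int(np.sum(areas <= observed))
    elif alternative == "two-sided":
        count = int(np.sum(np.abs(areas) >= abs(observed)))
    else:
        raise ValueError("alternative must be 'delay' or 'two-sided'")
    return (1 + count) / (1 + n)


def test_rt_delay(
    deletion_profiles: list[BinnedTrack],
    control_profiles: list[BinnedTrack] | None,
    query: Region,
    blacklist: tuple[Region, ...] | list[Region] = (),
    n_random: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    alternative: str = "delay",
    max_missing_frac: float = 0.2,
    all_wt_profiles: list[BinnedTrack] | None = None,
    return_null: bool = False,
):
    """Randomization test for deletion-induced RT delay over *query*.

    Replicate profiles of each allele are averaged, the ΔRT curve and its
    signed area over the query are computed, and the area is compared
    with the areas of ``n_random`` size-matched random regions sampled
    from the same genome-wide ΔRT curve, excluding the blacklist.

    Clones without an internal control (``control_profiles=None``) use the
    aggregate of ``all_wt_profiles`` and record ``control_mode="aggregate"``.
    """
    if not deletion_profiles:
        raise ValueError("no deletion-allele profiles")
    del_avg = average_tracks(deletion_profiles)
    if control_profiles:
        con_avg = average_tracks(control_profiles)
        control_mode = "internal"
    else:
        if not all_wt_profiles:
            raise ValueError(
                "clone lacks an internal control and no WT profiles were "
                "provided for the aggregate control"
            )
        con_avg = aggregate_wt_control(all_wt_profiles)
        control_mode = "aggregate"
    curve = delta_curve(del_avg, con_avg)
    observed = area_between(curve, query)
    regions = sample_null_regions(
        curve.genome, query.length, n_random, blacklist=blacklist, seed=seed,
        curve=curve, max_missing_frac=max_missing_frac,
    )
    null = null_area_distribution(curve, regions, seed=seed,
                                  blacklist=tuple(blacklist))
    p = empirical_pvalue(observed, null, alternative=alternative)
    result = SignifResult(
        delta_area=observed, pvalue=p, n_random=n_random, query=query,
        kind="delay", alpha=alpha, control_mode=control_mode, seed=seed,
    )
    return (result, null) if return_null else result


def test_delta_delta(
    clone1: tuple[list[BinnedTrack], list[BinnedTrack]],
    clone2: tuple[list[BinnedTrack], list[BinnedTrack]],
    query: Region,
    blacklist: tuple[Region, ...] | list[Region] = (),
    n_random: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    max_missing_frac: float = 0.2,
    return_null: bool = False,
):
    """Two-sided randomization test of ΔΔRT = ΔRT1 − ΔRT2 over *query*.

    Each clone is a (deletion_profiles, control_profiles) pair; whether
    two deletions delay RT equivalently is a directionless question, so
    the test is two-sided.
    """
    curves = []
    for del_profiles, con_profiles in (clone1, clone2):
        if not del_profiles or not con_profiles:
            raise ValueError("each clone needs deletion and control profiles")
        curves.append(
            delta_curve(average_tracks(del_profiles), average_tracks(con_profiles))
        )
    dd = curves[0].copy(stage="delta", meta={"kind": "delta_delta"})
    for chrom in dd.chroms:
        dd.data[chrom] = curves[0].data[chrom] - curves[1].data[chrom]
    observed = area_between(dd, query)
    regions = sample_null_regions(
        dd.genome, query.length, n_random, blacklist=blacklist, seed=seed,
        curve=dd, max_missing_frac=max_missing_frac,
    )
    null = null_area_distribution(dd, regions, seed=seed,
                                  blacklist=tuple(blacklist))
    p = empirical_pvalue(observed, null, alternative="two-sided")
    result = SignifResult(
        delta_area=observed, pvalue=p, n_random=n_random, query=query,
        kind="delta_delta", alpha=alpha, seed=seed,
    )
    return (result, null) if return_null else result
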