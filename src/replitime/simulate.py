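"""Synthetic allele-specific Repli-seq and nascent-transcription data.

The generator emulates the structure of two-allele (hybrid) Repli-seq
experiments: a smooth, domain-scale replication-timing (RT) landscape
shared by both alleles; an engineered deletion on one allele that imposes
an RT delay over a query domain; allele-specific-RT regions (a blacklist
for the randomization background); hemizygous deletion footprints with
zero coverage on the deleted allele; Poisson-Binomial count noise scaling
with sequencing depth; and 1 kb nascent-transcription coverage over gene
bodies.

Every stochastic stage draws from a child generator fanned out from one
master seed with a fixed stage key, so stages are independently
reproducible and a dataset is bitwise-deterministic given its
:class:`TruthSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .genome import Genome, Region, make_genome
from .track import BinnedTrack

__all__ = [
    "TruthSpec",
    "SimulatedDataset",
    "rng_for",
    "simulate_rt_field",
    "apply_allele_effects",
    "simulate_repliseq_counts",
    "simulate_bru_coverage",
    "simulate_dataset",
    "default_genome",
    "default_truth",
    "default_genes",
    "simulate_default",
    "CONTROL_ALLELE",
    "DELETION_ALLELE",
]

# allele labels mirror the maternal/paternal haplotypes of a hybrid line
CONTROL_ALLELE = "mus"
DELETION_ALLELE = "cas"

# fixed stage keys for the counter-based seed fan-out
_STAGE_FIELD = 0
_STAGE_COUNTS = 1
_STAGE_BRU = 2


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Child generator for (seed, stage key): counter-based fan-out."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for one simulated dataset.

    Parameters
    ----------
    query_domain : Region
        The domain whose RT the engineered deletion delays.
    delay : float
        RT delay in log2(E/L) units (>= 0) subtracted from the deletion
        allele over the query domain.
    length_scale : float
        Correlation length of the RT landscape in bp.  The field's
        autocorrelation is exp(-d^2 / (2 * length_scale^2)).
    amplitude : float
        Standard deviation of the RT landscape in log2(E/L) units.
    deletion_footprints : tuple of Region
        Missing sequence on the deletion allele: zero counts in both
        fractions over these regions.
    blacklist : tuple of Region
        Regions with allele-specific RT, excluded from the randomization
        background downstream.
    blacklist_offsets : tuple of float
        Per-region log2 offset added to the deletion allele's RT.
    depth : float
        Expected total reads per bin per fraction.
    n_replicates : int
        Replicates per allele.
    overdispersion : float
        Multiplier on the Poisson variance of per-bin totals (1 = Poisson);
        exposed for robustness experiments.
    seed : int
        Master seed; all stages derive child seeds from it.
    noise_seed : int or None
        Separate master seed for the count/coverage noise stages; defaults
        to ``seed``.  Clones of the same cell line share one genome and
        hence one RT landscape, so multi-clone experiments are simulated
        with a common ``seed`` (the landscape) and distinct ``noise_seed``
        values (independent sequencing noise).
    """

    query_domain: Region
    delay: float = 0.0
    length_scale: float = 400_000.0
    amplitude: float = 1.0
    deletion_footprints: tuple[Region, ...] = ()
    blacklist: tuple[Region, ...] = ()
    blacklist_offsets: tuple[float, ...] = ()
    depth: float = 2_000.0
    n_replicates: int = 2
    overdispersion: float = 1.0
    seed: int = 0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if len(self.blacklist) != len(self.blacklist_offsets):
            raise ValueError("blacklist and blacklist_offsets must align")
        for bl in self.blacklist:
            if bl.overlaps(self.query_domain):
                raise ValueError("blacklist must be disjoint from query domain")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["query_domain"] = _region_dict(self.query_domain)
        d["deletion_footprints"] = [_region_dict(r) for r in self.deletion_footprints]
        d["blacklist"] = [_region_dict(r) for r in self.blacklist]
        d["blacklist_offsets"] = list(self.blacklist_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSpec":
        d = dict(d)
        d["query_domain"] = _region_from_dict(d["query_domain"])
        d["deletion_footprints"] = tuple(
            _region_from_dict(r) for r in d.get("deletion_footprints", [])
        )
        d["blacklist"] = tuple(_region_from_dict(r) for r in d.get("blacklist", []))
        d["blacklist_offsets"] = tuple(d.get("blacklist_offsets", []))
        return cls(**d)


def _region_dict(r: Region) -> dict:
    return {"chrom": r.chrom, "start": r.start, "end": r.end, "label": r.label}


def _region_from_dict(d: dict) -> Region:
    return Region(d["chrom"], d["start"], d["end"], d.get("label"))


@dataclass
class SimulatedDataset:
    """Counts, coverage and ground truth for one simulated experiment.

    ``counts`` maps (allele, replicate, fraction) to an integer-valued
    count track; ``bru`` maps allele to a 1 kb coverage track.
    """

    genome: Genome
    truth: TruthSpec
    rt_true: dict[str, BinnedTrack]  # allele -> true RT field (with effects)
    counts: dict[tuple[str, int, str], BinnedTrack] = field(default_factory=dict)
    bru: dict[str, BinnedTrack] = field(default_factory=dict)

    @property
    def alleles(self) -> tuple[str, str]:
        return (CONTROL_ALLELE, DELETION_ALLELE)

    @property
    def replicates(self) -> range:
        return range(1, self.truth.n_replicates + 1)


# ---------------------------------------------------------------------------
# field and allele effects
# ---------------------------------------------------------------------------

def simulate_rt_field(
    genome: Genome,
    length_scale: float = 400_000.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> BinnedTrack:
    """Smooth random RT landscape shared by both alleles.

    Per chromosome, white Gaussian noise is convolved (circularly, which
    keeps the process exactly stationary) with a Gaussian kernel and
    rescaled so that the field has standard deviation ``amplitude`` and
    autocorrelation exp(-d^2 / (2 * length_scale^2)) at lag d.
    """
    if length_scale < genome.bin_size:
        raise ValueError("length_scale must be >= bin_size")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = rng_for(seed, _STAGE_FIELD)
    # correlation length L of the field needs kernel sigma = L / sqrt(2):
    # convolving with a Gaussian doubles the squared width of the
    # autocovariance.
    sigma_bins = (length_scale / genome.bin_size) / np.sqrt(2.0)
    data = {}
    for chrom in genome.names:
        n = genome.n_bins(chrom)
        white = rng.standard_normal(n)
        smooth = gaussian_filter1d(white, sigma_bins, mode="wrap")
        # unit-variance normalization via the discrete kernel's L2 norm
        impulse = np.zeros(n)
        impulse[n // 2] = 1.0
        kernel = gaussian_filter1d(impulse, sigma_bins, mode="wrap")
        norm = np.sqrt(np.sum(kernel**2))
        data[chrom] = amplitude * smooth / norm
    return BinnedTrack(genome, data=data, stage="smoothed", meta={"kind": "true_rt"})


def apply_allele_effects(
    field: BinnedTrack, truth: TruthSpec
) -> tuple[BinnedTrack, BinnedTrack]:
    """Derive per-allele true RT from the shared landscape.

    The control allele equals the field everywhere.  The deletion allele
    is delayed by ``truth.delay`` over the query domain (RT delay = lower
    log2(E/L)) and offset by each blacklist region's allele-specific
    offset.  Bin membership uses the midpoint rule.
    """
    genome = field.genome
    genome.validate_region(truth.query_domain)
    for r in truth.deletion_footprints + truth.blacklist:
        genome.validate_region(r)
    allele1 = field.copy(meta={"allele": CONTROL_ALLELE, "kind": "true_rt"})
    allele2 = field.copy(meta={"allele": DELETION_ALLELE, "kind": "true_rt"})
    q = genome.midpoint_bins(truth.query_domain, field.bin_size)
    allele2.data[truth.query_domain.chrom][q] -= truth.delay
    for region, offset in zip(truth.blacklist, truth.blacklist_offsets):
        sl = genome.midpoint_bins(region, field.bin_size)
        allele2.data[region.chrom][sl] += offset
    return allele1, allele2


# ---------------------------------------------------------------------------
# count and coverage noise
# ---------------------------------------------------------------------------

def simulate_repliseq_counts(
    rt: BinnedTrack,
    depth: float,
    seed: int = 0,
    deletions: tuple[Region, ...] | list[Region] = (),
    overdispersion: float = 1.0,
) -> tuple[BinnedTrack, BinnedTrack]:
    """Early/late count tracks whose binomial logit matches the RT field.

    Per bin the total N ~ Poisson(depth) and early ~ Binomial(N, p) with
    p = 2^rt / (1 + 2^rt), so E[log2(early/late)] -> rt at high depth.
    Bins overlapping a deletion footprint get N = 0 in both fractions.
    ``overdispersion`` > 1 inflates the total-count variance by gamma
    mixing of the Poisson rate.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if overdispersion < 1:
        raise ValueError("overdispersion must be >= 1")
    genome = rt.genome
    for r in deletions:
        genome.validate_region(r)
    rng = rng_for(seed, _STAGE_COUNTS)
    early_data, late_data = {}, {}
    for chrom in genome.names:
        values = rt.data[chrom]
        n = values.size
        if overdispersion > 1:
            # N ~ Poisson(Gamma) with Var = overdispersion * depth
            shape = depth / (overdispersion - 1)
            rate = rng.gamma(shape, (overdispersion - 1), size=n)
            total = rng.poisson(rate)
        else:
            total = rng.poisson(depth, size=n)
        p = 1.0 / (1.0 + np.exp2(-values))
        early = rng.binomial(total, p)
        late = total - early
        early_data[chrom] = early.astype(float)
        late_data[chrom] = late.astype(float)
    for r in deletions:
        sl = genome.overlapping_bins(r, rt.bin_size)
        early_data[r.chrom][sl] = 0.0
        late_data[r.chrom][sl] = 0.0
    meta = dict(rt.meta)
    early_t = BinnedTrack(genome, early_data, stage="counts",
                          meta={**meta, "fraction": "early"})
    late_t = BinnedTrack(genome, late_data, stage="counts",
                         meta={**meta, "fraction": "late"})
    return early_t, late_t


def simulate_bru_coverage(
    genome: Genome,
    genes: dict[str, Region],
    expression: dict[str, float],
    noise_cv: float = 0.1,
    seed: int = 0,
    bin_size: int = 1_000,
) -> BinnedTrack:
    """1 kb nascent-transcription coverage over gene bodies.

    Per bin inside gene *g* the signal is max(0, Normal(e_g, cv * e_g));
    zero outside gene bodies.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = rng_for(seed, _STAGE_BRU)
    track = BinnedTrack.zeros(genome, stage="coverage", bin_size=bin_size)
    for name, region in genes.items():
        genome.validate_region(region)
        level = float(expression.get(name, 0.0))
        if level < 0:
            raise ValueError(f"expression for {name} must be >= 0")
        sl = genome.midpoint_bins(region, bin_size)
        n = sl.stop - sl.start
        if level == 0 or n == 0:
            continue
        vals = rng.normal(level, noise_cv * level, size=n)
        track.data[region.chrom][sl] = np.maximum(vals, 0.0)
    return track


# ---------------------------------------------------------------------------
# whole-dataset assembly and the default fixture
# ---------------------------------------------------------------------------

def simulate_dataset(
    genome: Genome,
    truth: TruthSpec,
    genes: dict[str, Region] | None = None,
    expression: dict[str, dict[str, float]] | None = None,
    noise_cv: float = 0.1,
) -> SimulatedDataset:
    """Full two-allele dataset: counts per allele x replicate x fraction.

    ``expression`` maps allele -> gene -> level; when omitted no Bru
    coverage is generated.
    """
    field_track = simulate_rt_field(
        genome, truth.length_scale, truth.amplitude, seed=truth.seed
    )
    rt_con, rt_del = apply_allele_effects(field_track, truth)
    ds = SimulatedDataset(
        genome=genome,
        truth=truth,
        rt_true={CONTROL_ALLELE: rt_con, DELETION_ALLELE: rt_del},
    )
    noise_seed = truth.seed if truth.noise_seed is None else truth.noise_seed
    for a_idx, (allele, rt) in enumerate(
        ((CONTROL_ALLELE, rt_con), (DELETION_ALLELE, rt_del))
    ):
        dels = truth.deletion_footprints if allele == DELETION_ALLELE else ()
        for rep in range(1, truth.n_replicates + 1):
            child = int(
                rng_for(noise_seed, _STAGE_COUNTS, a_idx, rep).integers(2**31)
            )
            early, late = simulate_repliseq_counts(
                rt, truth.depth, seed=child, deletions=dels,
                overdispersion=truth.overdispersion,
            )
            for frac, t in (("early", early), ("late", late)):
                t.meta.update(
                    {"clone": "sim", "allele": allele, "replicate": rep,
                     "fraction": frac}
                )
                ds.counts[(allele, rep, frac)] = t
    if genes is not None and expression is not None:
        for a_idx, allele in enumerate(ds.alleles):
            child = int(rng_for(noise_seed, _STAGE_BRU, a_idx).integers(2**31))
            ds.bru[allele] = simulate_bru_coverage(
                genome, genes, expression.get(allele, {}),
                noise_cv=noise_cv, seed=child,
            )
            ds.bru[allele].meta.update({"clone": "sim", "allele": allele})
    return ds


def default_genome() -> Genome:
    """3 chromosomes x 60 Mb on a 50 kb grid."""
    return make_genome(3, 60_000_000, bin_size=50_000)


def default_truth(seed: int = 0, delay: float = 0.0, depth: float = 2_000.0,
                  n_replicates: int = 2, noise_seed: int | None = None,
                  with_footprint: bool = False) -> TruthSpec:
    """Standard fixture: one 2 Mb query domain and two ~2 Mb
    allele-specific-RT blacklist regions on other chromosomes.

    ``with_footprint`` adds a 150 kb hemizygous deletion footprint inside
    the query (zero coverage on the deletion allele), used when exercising
    missing-data handling and deletion detection.
    """
    footprints = (
        (Region("chr1", 20_900_000, 21_050_000, label="footprint"),)
        if with_footprint else ()
    )
    return TruthSpec(
        query_domain=Region("chr1", 20_000_000, 22_000_000, label="query"),
        delay=delay,
        deletion_footprints=footprints,
        blacklist=(
            Region("chr2", 10_000_000, 12_000_000, label="asrt1"),
            Region("chr3", 30_000_000, 32_000_000, label="asrt2"),
        ),
        blacklist_offsets=(0.8, -0.8),
        depth=depth,
        n_replicates=n_replicates,
        seed=seed,
        noise_seed=noise_seed,
    )


def default_genes() -> dict[str, Region]:
    """Three genes inside the query domain: one long gene and two short
    ones, mirroring a pluripotency-domain gene layout."""
    return {
        "geneL": Region("chr1", 20_100_000, 21_100_000, label="geneL"),
        "geneS1": Region("chr1", 21_300_000, 21_330_000, label="geneS1"),
        "geneS2": Region("chr1", 21_400_000, 21_425_000, label="geneS2"),
    }


def simulate_default(
    seed: int = 0,
    delay: float = 0.0,
    depth: float = 2_000.0,
    n_replicates: int = 2,
    with_bru: bool = False,
    expression_scale: dict[str, float] | None = None,
    noise_seed: int | None = None,
    with_footprint: bool = False,
) -> SimulatedDataset:
    """Simulate the standard fixture.

    ``expression_scale`` maps gene name -> multiplier applied to the
    deletion allele's baseline expression (knockdown fractions).
    """
    genome = default_genome()
    truth = default_truth(seed=seed, delay=delay, depth=depth,
                          n_replicates=n_replicates, noise_seed=noise_seed,
                          with_footprint=with_footprint)
    genes = expression = None
    if with_bru:
        genes = default_genes()
        base = {"geneL": 8.0, "geneS1": 20.0, "geneS2": 15.0}
        scale = expression_scale or {}
        expression = {
            CONTROL_ALLELE: dict(base),
            DELETION_ALLELE: {
                g: level * scale.get(g, 1.0) for g, level in base.items()
            },
        }
    return simulate_dataset(genome, truth, genes=genes, expression=expression)
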