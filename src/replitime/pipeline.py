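"""End-to-end conveniences: simulated dataset in, significance result out."""

from __future__ import annotations

from .processing import ProcessingConfig, process_dataset
from .simulate import CONTROL_ALLELE, DELETION_ALLELE, SimulatedDataset
from .stats import SignifResult, test_delta_delta, test_rt_delay

__all__ = ["delay_analysis", "delta_delta_analysis", "clone_profiles"]


def clone_profiles(dataset: SimulatedDataset, config: ProcessingConfig | None = None):
    """Process a dataset and split smoothed profiles by allele."""
    processed = process_dataset(dataset, config=config or ProcessingConfig())
    dels = [processed[(DELETION_ALLELE, r)] for r in dataset.replicates]
    cons = [processed[(CONTROL_ALLELE, r)] for r in dataset.replicates]
    return dels, cons


def delay_analysis(
    dataset: SimulatedDataset,
    n_random: int = 10_000,
    seed: int = 0,
    config: ProcessingConfig | None = None,
) -> SignifResult:
    """Process a simulated clone and test its RT delay over the true query."""
    dels, cons = clone_profiles(dataset, config)
    return test_rt_delay(
        dels, cons, dataset.truth.query_domain,
        blacklist=dataset.truth.blacklist, n_random=n_random, seed=seed,
    )


def delta_delta_analysis(
    dataset1: SimulatedDataset,
    dataset2: SimulatedDataset,
    n_random: int = 10_000,
    seed: int = 0,
    config: ProcessingConfig | None = None,
) -> SignifResult:
    """Process two simulated clones and run the two-sided ΔΔRT test."""
    pair1 = clone_profiles(dataset1, config)
    pair2 = clone_profiles(dataset2, config)
    return test_delta_delta(
        pair1, pair2, dataset1.truth.query_domain,
        blacklist=dataset1.truth.blacklist, n_random=n_random, seed=seed,
    )
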