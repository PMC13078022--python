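"""Shared fixtures: a tiny hand-built variant universe and simulated cohorts."""

import pytest

from mfclone.simulate import SimulationConfig, simulate_cohort
from mfclone.types import GenomeBins, MutationProfile, VariantCall


def profile_from_labels(biopsy_id, labels, label_freqs, label_calls):
    """MutationProfile over a shared label -> VariantCall universe."""
    variants = {label_calls[l].variant_key: label_calls[l] for l in labels}
    cohort_freq = {label_calls[l].variant_key: f for l, f in label_freqs.items()}
    return MutationProfile(biopsy_id=biopsy_id, variants=variants,
                           cohort_freq=cohort_freq)


@pytest.fixture
def label_universe():
    """Five named variants with fixed frequencies for hand calculations."""
    calls = {
        "v1": VariantCall(chrom="1", pos=100, ref="A", alt="T", gene="CTNNB1"),
        "v2": VariantCall(chrom="2", pos=200, ref="C", alt="G", gene="TP53"),
        "v3": VariantCall(chrom="3", pos=300, ref="G", alt="A", gene="ALB"),
        "v4": VariantCall(chrom="4", pos=400, ref="T", alt="C"),
        "v5": VariantCall(chrom="5", pos=500, ref="A", alt="G"),
    }
    freqs = {"v1": 0.01, "v2": 0.1, "v3": 0.1, "v4": 0.05, "v5": 0.02}
    return calls, freqs


@pytest.fixture
def small_bins():
    return GenomeBins(
        chroms=("1", "1", "1", "2", "2"),
        starts=(0, 100, 200, 0, 100),
        ends=(100, 200, 300, 100, 200),
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """A small deterministic simulated cohort with all layers."""
    cfg = SimulationConfig(n_IM=2, n_MO=2, n_mixed=1, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-size cohort (10 IM / 9 MO / 3 mixed) used by several suites."""
    cfg = SimulationConfig(seed=7)
    return simulate_cohort(cfg)
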