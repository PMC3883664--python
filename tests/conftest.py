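"""Shared fixtures: threshold config, call builders, and a small simulated cohort."""

from pathlib import Path

import numpy as np
import pytest

from wgaconcord import CohortConfig, ThresholdConfig, VariantCall, simulate_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def thr() -> ThresholdConfig:
    return ThresholdConfig()


def make_call(chrom="chr1", pos=100, ref="A", alt="G", genotype="het",
              depth=30, alt_depth=15, qual=50.0) -> VariantCall:
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype,
                       depth=depth, alt_depth=alt_depth, qual=qual)


def random_calls(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                 max_pos=100_000):
    """Distinct-position random SNV calls for oracle tests."""
    bases = "ACGT"
    calls = []
    seen = set()
    while len(calls) < n:
        chrom = chroms[rng.integers(0, len(chroms))]
        pos = int(rng.integers(1, max_pos))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref = bases[rng.integers(0, 4)]
        alt = bases[rng.integers(0, 4)]
        while alt == ref:
            alt = bases[rng.integers(0, 4)]
        depth = int(rng.integers(0, 80))
        calls.append(VariantCall(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            genotype="het" if rng.random() < 0.6 else "hom_alt",
            depth=depth, alt_depth=int(rng.integers(0, depth + 1)),
            qual=float(np.round(rng.uniform(0, 80), 1))))
    return calls


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory) -> Path:
    """A small simulated cohort written to disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("cohort")
    simulate_cohort(CohortConfig.small(seed=123), outdir=outdir)
    return outdir


@pytest.fixture(scope="session")
def small_cohort():
    """The same small cohort, in memory (fresh object, same seed)."""
    return simulate_cohort(CohortConfig.small(seed=123))
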