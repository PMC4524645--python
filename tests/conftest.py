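import numpy as np
import pandas as pd
import pytest

import pmeth
from pmeth.io import as_cpg_track

ACCEPT_SEED = 0  # single seed used by the simulation-based checks


@pytest.fixture(scope="session")
def demo_bundle():
    return pmeth.simulate_genome(pmeth.demo_genome_spec(seed=ACCEPT_SEED))


@pytest.fixture(scope="session")
def demo_methylome(demo_bundle):
    """Full demo methylome: domains + gene-body elevation + island override."""
    return pmeth.simulate_methylome(
        demo_bundle, pmeth.demo_methylome_spec(seed=ACCEPT_SEED)
    )


@pytest.fixture(scope="session")
def domains_methylome(demo_bundle):
    """Domains-only methylome (no elevation, no island override)."""
    return pmeth.simulate_methylome(
        demo_bundle, pmeth.demo_methylome_spec(seed=ACCEPT_SEED, domains_only=True)
    )


@pytest.fixture(scope="session")
def ref_track_20kb(demo_bundle, demo_methylome):
    return pmeth.window_methylation(
        demo_methylome.calls, 20_000, 20, chrom_sizes=demo_bundle.chrom_sizes
    )


def seg_with_boundaries(bpos, chrom="chr1", span=10_000_000):
    """A DomainSegmentation whose interior boundaries sit at given positions
    (alternating PMD/HMD domains covering [0, span))."""
    from pmeth.segmentation import DomainSegmentation

    edges = [0] + sorted(int(b) for b in bpos) + [span]
    rows = []
    for i in range(len(edges) - 1):
        rows.append(
            {
                "chrom": chrom, "start": edges[i], "end": edges[i + 1],
                "state": "PMD" if i % 2 == 0 else "HMD",
                "mean_meth": 0.4 if i % 2 == 0 else 0.8,
                "n_windows": max(1, (edges[i + 1] - edges[i]) // 20_000),
            }
        )
    return DomainSegmentation(
        domains=pd.DataFrame(rows), state_means={"PMD": 0.4, "HMD": 0.8},
        state_sds={"PMD": 0.03, "HMD": 0.03}, log_likelihood=0.0,
        converged=True, no_pmd_structure=False,
    )


def random_cpg_track(rng, n=50, chroms=("chr1", "chr2"), with_counts=True):
    chrom = rng.choice(chroms, size=n)
    pos = rng.integers(0, 1_000_000, size=n)
    # unique (chrom, pos)
    df = pd.DataFrame({"chrom": chrom, "pos": pos}).drop_duplicates()
    total = rng.integers(1, 30, size=len(df)).astype(float)
    meth = rng.binomial(total.astype(int), rng.random(len(df))).astype(float)
    if with_counts:
        df["meth_reads"] = meth
        df["total_reads"] = total
    else:
        df["fraction"] = np.round(rng.random(len(df)), 6)
    return as_cpg_track(df)
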