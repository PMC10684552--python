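import numpy as np
import pytest

from bovscan.panel import HaplotypePanel, PopulationMap


def build_panel(
    rng,
    n_samples=8,
    n_sites=50,
    length=100_000,
    contig="chr1",
    p=0.4,
    haplotypes=None,
    positions=None,
):
    """Random (or explicit) biallelic phased panel for unit tests."""
    if positions is None:
        positions = np.sort(
            rng.choice(np.arange(1, length + 1), size=n_sites, replace=False)
        )
    else:
        positions = np.asarray(positions)
        n_sites = len(positions)
    if haplotypes is None:
        haplotypes = (rng.random((2 * n_samples, n_sites)) < p).astype(np.int8)
    else:
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        n_samples = haplotypes.shape[0] // 2
    samples = [f"s{i}" for i in range(n_samples)]
    return HaplotypePanel(
        contig=np.full(n_sites, contig, dtype=object),
        pos=positions,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        haplotypes=haplotypes,
        samples=samples,
        phased=True,
        contig_lengths={contig: length},
    )


def split_popmap(panel, n_pops=2, labels=None):
    """Assign the panel's samples round-robin-free (contiguous blocks) to pops."""
    labels = labels or [f"P{k}" for k in range(n_pops)]
    n = panel.n_samples
    per = n // len(labels)
    mapping = {}
    for i, s in enumerate(panel.samples):
        mapping[s] = labels[min(i // per, len(labels) - 1)]
    return PopulationMap(mapping)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def panel_factory():
    return build_panel


@pytest.fixture
def popmap_factory():
    return split_popmap
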