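"""Shared fixtures: hand-built toy matrices and small simulation configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from apomixis_scan.genotypes import GenotypeMatrix
from apomixis_scan.simulate import SimConfig


def make_matrix(
    calls,
    sample_ids=None,
    chrom="chr1",
    positions=None,
    depth=None,
    ad_ref=None,
    ad_alt=None,
    chrom_length=None,
    all_sites=False,
    multiallelic=None,
):
    """Build a GenotypeMatrix from a nested list of genotype codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n_samples)]
    positions = (
        np.asarray(positions) if positions is not None else np.arange(n_sites) * 100
    )
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "multiallelic": multiallelic if multiallelic is not None else False,
            "is_variant": True,
        }
    )
    lengths = {chrom: chrom_length or int(positions.max()) + 100}
    return GenotypeMatrix(
        sample_ids=sample_ids,
        sites=sites,
        calls=calls,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        ad_ref=None if ad_ref is None else np.asarray(ad_ref, dtype=np.int32),
        ad_alt=None if ad_alt is None else np.asarray(ad_alt, dtype=np.int32),
        all_sites=all_sites,
        chrom_lengths=lengths,
    )


@pytest.fixture
def small_config():
    """Desk-scale simulation config: 2 x 1 Mb chromosomes."""
    return SimConfig(n_chromosomes=2, chrom_length=1_000_000, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
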