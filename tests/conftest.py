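"""Shared fixtures: small synthetic panels, genotype matrices and databases."""

from __future__ import annotations

import numpy as np
import pytest

from ibdphase import (DatabaseSpec, GenotypeMatrix, SimConfig, SiteIndex,
                      make_database)


def uniform_panel(n_sites: int, spacing_cm: float = 0.05,
                  n_chrom: int = 1) -> SiteIndex:
    """Evenly spaced panel used by constructed-scenario tests."""
    per = n_sites // n_chrom
    chroms, poss, cms = [], [], []
    for c in range(n_chrom):
        chroms.extend([str(c + 1)] * per)
        poss.append(np.arange(per, dtype=np.int64) * 10_000 + 1)
        cms.append(np.arange(per) * spacing_cm)
    return SiteIndex(np.array(chroms, dtype=object), np.concatenate(poss),
                     np.concatenate(cms))


def random_genotypes(rng: np.random.Generator, samples: list[str],
                     n_sites: int, spacing_cm: float = 0.03,
                     missing_rate: float = 0.0) -> GenotypeMatrix:
    sites = uniform_panel(n_sites, spacing_cm)
    f = rng.uniform(0.05, 0.5, n_sites)
    calls = ((rng.random((len(samples), n_sites)) < f).astype(np.int8)
             + (rng.random((len(samples), n_sites)) < f).astype(np.int8))
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = -1
    return GenotypeMatrix(sites, samples, calls)


@pytest.fixture(scope="session")
def small_db():
    """A compact proband + relative database with simulation truth."""
    cfg = SimConfig(n_chrom=4, chrom_cm=60, spacing_cm=0.05, seed=3)
    return make_database(cfg, DatabaseSpec())
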