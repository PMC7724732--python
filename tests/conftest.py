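"""Shared fixtures: small simulated datasets and one session-scoped
end-to-end pipeline run reused by the integration checks."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from spermnet.datatypes import GenotypeMatrix


def make_genotypes(
    n: int, m: int, seed: int = 0, maf: float | np.ndarray = 0.3, chrom: str = "1"
) -> GenotypeMatrix:
    """Independent HWE genotypes (no LD) for estimator tests."""
    rng = np.random.default_rng(seed)
    p = np.broadcast_to(np.asarray(maf, dtype=float), (m,))
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": [chrom] * m,
            "bp": np.arange(1, m + 1) * 1000,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    samples = [f"i{i}" for i in range(n)]
    return GenotypeMatrix(pd.DataFrame(dos, index=samples, columns=snp_map["snp_id"]), snp_map)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run at the default study-scale configuration."""
    from spermnet import SimConfig, run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(SimConfig(seed=11))
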