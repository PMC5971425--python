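from __future__ import annotations

import numpy as np
import pytest

import commitpoint as cp


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One reduced synthetic cohort shared across the suite."""
    outdir = tmp_path_factory.mktemp("cohort")
    return cp.generate_cohort(cp.small_config(seed=11), outdir)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Pipeline results on the shared small cohort."""
    cfg = cp.PipelineConfig.from_yaml(small_cohort.pipeline_config)
    return cp.run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_peakset(rng, n, chrom_len, max_width=500, chroms=("chr1",), label="x"):
    """Random (possibly overlapping) intervals on toy chromosomes."""
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        w = int(rng.integers(1, max_width + 1))
        s = int(rng.integers(0, chrom_len - w))
        ivs.append(cp.Interval(chrom, s, s + w))
    return cp.PeakSet(tuple(ivs), label)


def coverage_mask(ps, chrom, chrom_len):
    """Boolean-array oracle of covered bases on one chromosome."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in ps:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask
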