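from __future__ import annotations

import pytest

from cdrscan.binning import BinnedProfile, MethylBin
from cdrscan.io import GenomicInterval, MethylRecord
from cdrscan.simulate import SimParams, simulate_region, write_fixture


def make_record(chrom="chrT", start=0, valid_cov=30, n_mod=None, freq=None,
                strand=".", mod_code="m", end=None):
    """Build a consistent MethylRecord from partial information."""
    if freq is None and n_mod is None:
        freq, n_mod = 0.5, valid_cov // 2
    elif n_mod is None:
        n_mod = round(freq * valid_cov)
        freq = n_mod / valid_cov if valid_cov else 0.0
    elif freq is None:
        freq = n_mod / valid_cov if valid_cov else 0.0
    return MethylRecord(chrom=chrom, start=start,
                        end=end if end is not None else start + 1,
                        mod_code=mod_code, strand=strand,
                        valid_cov=valid_cov, n_mod=n_mod, freq=freq)


def make_profile(values, alpha_mask=None, bin_size=5000, chrom="chrT",
                 region_start=0):
    """Profile whose i-th bin has mean_freq values[i] (None = no CpGs).

    alpha_mask defaults to all-alpha.
    """
    if alpha_mask is None:
        alpha_mask = [True] * len(values)
    bins = []
    for i, v in enumerate(values):
        iv = GenomicInterval(chrom, region_start + i * bin_size,
                             region_start + (i + 1) * bin_size)
        if v is None:
            bins.append(MethylBin(interval=iv, mean_freq=None, n_cpg=0,
                                  is_alpha=alpha_mask[i]))
        else:
            bins.append(MethylBin(interval=iv, mean_freq=float(v), n_cpg=10,
                                  is_alpha=alpha_mask[i],
                                  mean_valid_cov=30.0,
                                  mean_mod_cov=30.0 * float(v)))
    region = GenomicInterval(chrom, region_start,
                             region_start + len(values) * bin_size)
    return BinnedProfile(region=region, bin_size=bin_size, bins=bins)


@pytest.fixture(scope="session")
def small_sim_params():
    return SimParams(
        region_length=500_000,
        chrom="chrT",
        alpha_array=GenomicInterval("chrT", 100_000, 400_000),
        dip_intervals=((200_000, 280_000),),
        seed=11)


@pytest.fixture(scope="session")
def small_sim(small_sim_params):
    return simulate_region(small_sim_params)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_sim_params, small_sim):
    """A complete on-disk fixture set from the small simulation."""
    records, annotations, truth = small_sim
    out = tmp_path_factory.mktemp("fixture")
    write_fixture(records, annotations, truth, out,
                  region=small_sim_params.region)
    return out
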