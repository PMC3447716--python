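"""Shared fixtures: small simulated datasets built once per session."""

from types import SimpleNamespace

import numpy as np
import pytest

import bqrecal as bq


def _alt_for(seq: str, pos1: int) -> str:
    return next(b for b in "ACGT" if b != seq[pos1 - 1])


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """2,000 76-bp reads over a 20 kb reference (~7.6x coverage).

    Reported qualities are miscalibrated (true error probability 10x the
    reported one) with elevated error rates at read ends; 10 heterozygous
    variant sites are planted plus 2 systematic all-non-reference positions.
    """
    d = tmp_path_factory.mktemp("sim_small")
    ref = d / "ref.fasta"
    seq = bq.generate_reference(20_000, seed=11, out_path=ref)
    rng = np.random.default_rng(12)
    sites = rng.choice(np.arange(200, 19_800), size=12, replace=False)
    variant_sites = {int(p): (_alt_for(seq, int(p)), 0.5) for p in sites[:10]}
    systematic_sites = {int(p): _alt_for(seq, int(p)) for p in sites[10:]}
    spec = bq.ErrorModelSpec(
        seed=13, variant_sites=variant_sites, systematic_sites=systematic_sites
    )
    bam = d / "reads.bam"
    truth = bq.simulate_bam(ref, spec, 2_000, bam, d / "truth.tsv")
    return SimpleNamespace(
        dir=d,
        ref=ref,
        seq=seq,
        bam=bam,
        truth=truth,
        spec=spec,
        variant_sites=variant_sites,
        systematic_sites=systematic_sites,
        snp={("simchr", p) for p in variant_sites},
        region=bq.RegionSpec("simchr", 1, 20_000),
    )


@pytest.fixture(scope="session")
def training_small(sim_small):
    """Labeled, filtered training table for the small simulated dataset."""
    bases = bq.read_aligned_bases(sim_small.bam, sim_small.region, sim_small.ref)
    training, stats = bq.build_training_set(
        bases, bq.FilterParams(), snp_positions=sim_small.snp
    )
    return SimpleNamespace(bases=bases, training=training, stats=stats)


@pytest.fixture(scope="session")
def fitted_small(sim_small, training_small):
    """Fitted recalibration model for the small simulated dataset."""
    model = bq.BaseQualityModel(
        training_small.training, region=sim_small.region
    )
    return model.fit()
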