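"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from autozyg import (GenotypeMatrix, SampleTable, VariantMap,
                     inbreeding_profile, qc_filter, roh_sample_summary)
from autozyg.pipeline import cohort_config_from_dict
from autozyg.roh import call_roh
from autozyg.simulate import simulate_cohort

GENOME_BP = 20 * 30_000_000


def make_matrix(calls, pos=None, chrom=None, sample_ids=None) -> GenotypeMatrix:
    """Hand-rolled GenotypeMatrix from a plain call array."""
    calls = np.asarray(calls, dtype=np.int8)
    ns, nv = calls.shape
    pos = np.arange(1, nv + 1) * 1000 if pos is None else np.asarray(pos)
    chrom = np.array(["1"] * nv, dtype=object) if chrom is None \
        else np.asarray(chrom, dtype=object)
    vm = VariantMap(chrom, pos, np.array([f"v{i}" for i in range(nv)], dtype=object),
                    np.array(["A"] * nv, dtype=object),
                    np.array(["B"] * nv, dtype=object))
    st = SampleTable.anonymous(ns) if sample_ids is None else SampleTable(
        np.asarray(sample_ids, dtype=object),
        np.asarray(sample_ids, dtype=object),
        np.array(["0"] * ns, dtype=object), np.array(["0"] * ns, dtype=object),
        np.zeros(ns, dtype=np.int64))
    return GenotypeMatrix(calls, vm, st)


@pytest.fixture(scope="session")
def consang_cohort():
    """One mixed-consanguinity cohort with a recessive-load trait."""
    cfg = cohort_config_from_dict({
        "design": {"unrelated": 10, "first_cousin": 15, "avuncular": 8,
                   "full_sib": 7},
        "offspring_per_family": 3,
        "n_chrom": 20, "chrom_length_bp": 30_000_000, "snps_per_chrom": 1200,
        "traits": [{"name": "q1", "recessive": [[0.05, -4.0]] * 20,
                    "residual_sd": 1.0}],
    })
    return simulate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def consang_profile(consang_cohort):
    """QC'd genotypes, ROH calls and the full estimator table."""
    g, _ = qc_filter(consang_cohort.genotypes)
    segs = call_roh(g)
    summary = roh_sample_summary(segs, g.samples.sample_id)
    prof = inbreeding_profile(g, segs, summary, genome_size_bp=GENOME_BP)
    return g, segs, prof


@pytest.fixture(scope="session")
def random_mating_cohort():
    """Outbred cohort: the Hardy-Weinberg null for every estimator."""
    cfg = cohort_config_from_dict({
        "design": {"unrelated": 60}, "offspring_per_family": 1,
        "n_chrom": 10, "chrom_length_bp": 30_000_000, "snps_per_chrom": 800,
    })
    return simulate_cohort(cfg, seed=7)
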