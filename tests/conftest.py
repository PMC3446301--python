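"""Shared synthetic fixtures, built once per session.

Everything is generated in memory from fixed seeds; no data files ship with
the test suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from oriseq import features as ft
from oriseq.profile import ProfileParams, build_profile
from oriseq.synthetic import (
    SyntheticSpec,
    make_genome,
    simulate_nucleosome_reads,
    simulate_replication_reads,
)


@pytest.fixture(scope="session")
def mini_replication():
    """600-kb genome with 5 origins plus its profile: the small pipeline fixture."""
    spec = SyntheticSpec(
        chromosome_lengths=[600_000],
        n_origins=5,
        s_read_count=500_000,
        g2_read_count=500_000,
        seed=17,
    )
    genome, truth = make_genome(spec)
    s_reads, g2_reads = simulate_replication_reads(genome, truth, spec)
    prof = build_profile(
        s_reads,
        g2_reads,
        spec.chrom_lengths_dict(),
        ProfileParams(replicated_fraction_n=truth.replicated_fraction_n),
    )
    return {
        "spec": spec,
        "genome": genome,
        "truth": truth,
        "s_reads": s_reads,
        "g2_reads": g2_reads,
        "profile": prof,
    }


@pytest.fixture(scope="session")
def polyA_loci():
    """200 + 200 loci from a polyA-mode genome (origins used as peak anchors)."""
    spec = SyntheticSpec(
        chromosome_lengths=[3_000_000], n_origins=200, peak_sigma=1500, seed=5
    )
    genome, truth = make_genome(spec)
    loci = ft.extract_loci(truth.origin_positions, genome, truth.gene_intervals, seed=5)
    matrix = ft.build_feature_matrix(loci)
    return {"spec": spec, "genome": genome, "truth": truth, "loci": loci, "matrix": matrix}


@pytest.fixture(scope="session")
def gc_loci():
    """Same geometry in GC-motif mode, with the Sap1-like PWM as a motif column."""
    spec = SyntheticSpec(
        chromosome_lengths=[3_000_000],
        n_origins=200,
        peak_sigma=1500,
        species_mode="GC_motif",
        seed=6,
    )
    genome, truth = make_genome(spec)
    loci = ft.extract_loci(truth.origin_positions, genome, truth.gene_intervals, seed=6)
    from oriseq.synthetic import SAP1_LIKE_CONSENSUS

    pwm = ft.PWM.from_consensus("Sap1", SAP1_LIKE_CONSENSUS)
    matrix = ft.build_feature_matrix(loci, pwms=[pwm])
    return {"spec": spec, "genome": genome, "truth": truth, "loci": loci, "matrix": matrix, "pwm": pwm}


@pytest.fixture(scope="session")
def nucleosome_fixture():
    """1-Mb genome with origin and non-origin NFRs plus sampled occupancy."""
    from oriseq import nucleosome as nuc

    spec = SyntheticSpec(
        chromosome_lengths=[1_000_000], n_origins=8, nuc_read_count=700_000, seed=9
    )
    genome, truth = make_genome(spec)
    reads = simulate_nucleosome_reads(genome, truth, spec)
    occ = nuc.occupancy_from_reads(reads, spec.chrom_lengths_dict())
    nfrs = nuc.detect_nfrs(occ)
    return {"spec": spec, "truth": truth, "reads": reads, "occupancy": occ, "nfrs": nfrs}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
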