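"""Shared fixtures: one simulated locus and repertoire reused across tests."""

from __future__ import annotations

import pytest

from tralocus.annotate import annotate_locus
from tralocus.simulate import (
    LocusSpec,
    RepertoireSpec,
    simulate_locus,
    simulate_repertoire_reads,
)
from tralocus.subgroups import classify_locus


@pytest.fixture(scope="session")
def locus_sim():
    return simulate_locus(LocusSpec(rng_seed=0))


@pytest.fixture(scope="session")
def locus_annotation(locus_sim):
    ann = annotate_locus(locus_sim.genome, locus_sim.c_queries(),
                         contig=locus_sim.contig)
    classify_locus(ann)
    return ann


@pytest.fixture(scope="session")
def repertoire_sim(locus_sim):
    spec = RepertoireSpec(n_reads=800, substitution_error_rate=0.0, rng_seed=5)
    pairs, truth = simulate_repertoire_reads(locus_sim.germline_set(), spec,
                                             sample="fish1")
    return pairs, truth, spec


def core_set(annotations):
    """Comparable identity of a set of gene annotations."""
    return {a.core_tuple() for a in annotations}
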