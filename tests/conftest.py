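"""Shared fixtures: one synthetic sequencing run reused across tests."""

from __future__ import annotations

import pytest

from mirseq import simdata, preprocess, alignquant
from mirseq.io import iter_fastq


@pytest.fixture(scope="session")
def toy_genome():
    return simdata.generate_toy_genome(simdata.ToyGenomeSpec(rng_seed=7))


@pytest.fixture(scope="session")
def read_spec():
    return simdata.ReadSimSpec(
        planted_fold_changes={"mir-001": 4.0, "mir-002": 0.25},
        rng_seed=3)


@pytest.fixture(scope="session")
def sim_run(toy_genome, read_spec, tmp_path_factory):
    """Full synthetic run: simulate -> preprocess -> classify."""
    outdir = tmp_path_factory.mktemp("simrun")
    paths, truth = simdata.simulate_reads(toy_genome, read_spec, outdir)
    clean_libs = {}
    stats = {}
    for lib, path in paths.items():
        cp, st = preprocess.preprocess_library(path,
                                               read_spec.adapter_sequence)
        clean_libs[lib] = [(t.split()[0], s) for t, s, _ in iter_fastq(cp)]
        stats[lib] = st
    class_counts, matrix, genome_hits = alignquant.classify_and_count(
        clean_libs, toy_genome.mature, toy_genome.trna, toy_genome.rrna,
        read_spec.adapter_sequence, toy_genome.genome,
        toy_genome.known_mirna_bed())
    return {
        "toy": toy_genome, "spec": read_spec, "paths": paths,
        "truth": truth, "clean_libs": clean_libs, "stats": stats,
        "class_counts": class_counts, "matrix": matrix,
        "genome_hits": genome_hits,
    }
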