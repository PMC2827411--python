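"""Shared fixtures: a seeded synthetic world and random toy collections."""

from __future__ import annotations

import numpy as np
import pytest

from remapkit.annotation_io import SourceDB, TranscriptCollection, TranscriptRecord
from remapkit.gene_definition import LinkageMethod, cluster_transcripts
from remapkit.probe_remapper import (
    classify_and_group,
    match_probes,
    rescue_junction_probes,
)
from remapkit.synthetic_fixtures import SimConfig, simulate_annotation, simulate_probes


def make_transcript(tid: str, exons, strand: str = "+", chrom: str = "chr1",
                    cds=None, source=SourceDB.OTHER) -> TranscriptRecord:
    """Small constructor for hand-built transcripts in tests."""
    exons = tuple(sorted(exons))
    tx_start, tx_end = exons[0][0], exons[-1][1]
    if cds is None:
        cds = (tx_start, tx_end)  # fully coding by default
    return TranscriptRecord(
        transcript_id=tid,
        source_db=source,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exons=exons,
        cds_start=cds[0],
        cds_end=cds[1],
    )


def random_toy_collection(seed: int, n: int = 50) -> TranscriptCollection:
    """Random transcripts on two chromosomes/both strands, ~20% non-coding."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, 3))}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 5))
        pos = int(rng.integers(0, 50_000))
        exons = []
        for _ in range(n_ex):
            ln = int(rng.integers(30, 300))
            exons.append((pos, pos + ln))
            pos += ln + int(rng.integers(20, 500))
        cs = exons[0][0] + int(rng.integers(0, 20))
        ce = exons[-1][1] - int(rng.integers(0, 20))
        if cs >= ce or rng.random() < 0.2:
            cs = ce = exons[0][0]  # non-coding
        recs.append(
            TranscriptRecord(f"t{i}", SourceDB.OTHER, chrom, strand,
                             exons[0][0], exons[-1][1], tuple(exons), cs, ce)
        )
    return TranscriptCollection(tuple(recs))


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_world(sim_config):
    """Default synthetic world: annotation, planted probes, and truth."""
    annotation = simulate_annotation(sim_config)
    probes, truth = simulate_probes(sim_config, annotation)
    return annotation, probes, truth


def run_remap(annotation, probes, min_probes: int = 3,
              method: LinkageMethod = LinkageMethod.EXLINK):
    """Full remapping pipeline on a simulated world."""
    genes = cluster_transcripts(annotation.collection, method)
    hits = match_probes(probes, annotation.genome)
    matched = {h.probe_id for h in hits}
    unmatched = [p for p in probes if p.probe_id not in matched]
    hits = hits + rescue_junction_probes(unmatched, annotation.collection, annotation.genome)
    return classify_and_group(probes, hits, genes, annotation.collection,
                              min_probes=min_probes)


@pytest.fixture(scope="session")
def sim_remapping(sim_world):
    annotation, probes, _ = sim_world
    return run_remap(annotation, probes)
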