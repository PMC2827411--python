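"""Synthetic genomes, annotations, probes, and expression with planted truth.

The generator emits a toy world shaped like the remapping problem: a random
genome carrying gene scaffolds whose transcript variants discriminate the
four gene-definition rules, multi-database views produced by per-database
transcript dropout, probe tables with an exact planted count per
classification category, and expression matrices with planted isoform
switches. Every planted quantity is recorded in a machine-readable
:class:`TruthSet`; planted categories are constructed, never
rejection-sampled, so truth counts are exact.

Scaffold roles (default world, 12 genes):

* good hosts (3)      — constitutive-exon probe sets (signature = all
  transcripts); host 0 also carries one reverse-complement (``_RC``) set;
  their introns host the intronic probes.
* junction host (1)   — probes spanning an exon-exon junction present in
  one transcript only; rescued via spliced sequences.
* orphan hosts (2)    — 1-2 probe groups on a cassette exon unique to one
  transcript (fail the minimum probe-set size).
* antisense pair (2)  — opposite-strand genes with overlapping exons;
  probes in the overlap interrogate two genes (MULTI_GENE under every
  strand-restricted definition).
* decoy pair (2)      — same-strand genes overlapping only in UTR exons:
  one gene under OVERLAP_0, two under EXLINK/EXBD/ITBD.
* single-exon (1)     — ITBD singleton by construction.
* itbd-split (1)      — a retained-intron single-exon variant that stays
  linked under EXLINK/OVERLAP_0 but splits off under ITBD and EXBD.

A duplicated intergenic block provides MULTI_GENOME probes; random 25-mers
absent from the genome provide NO_GENOME probes. One seeded generator
drives all sampling.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import SourceDB, TranscriptCollection, TranscriptRecord
from .gene_definition import LinkageMethod, linked
from .probe_remapper import (
    ProbeClass,
    ProbeRecord,
    ProbeSetDefinition,
    RemappingResult,
    AccountingTable,
    Sense,
    reverse_complement,
    spliced_sequence,
)
from .splicing_index import ExpressionMatrix

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class PlantedProbeCounts:
    """Exact numbers of probes planted per classification category."""

    multi_genome: int = 5
    no_genome: int = 5
    multi_gene: int = 5
    intergenic: int = 5
    intronic: int = 5
    orphan_groups: int = 2
    orphan_group_size: int = 2
    good_sets: int = 3
    probes_per_good_set: int = 4
    junction_sets: int = 1
    probes_per_junction_set: int = 3
    antisense_sets: int = 1
    probes_per_antisense_set: int = 3

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def good_total(self) -> int:
        return (
            self.good_sets * self.probes_per_good_set
            + self.junction_sets * self.probes_per_junction_set
            + self.antisense_sets * self.probes_per_antisense_set
        )

    @property
    def underpopulated_total(self) -> int:
        return self.orphan_groups * self.orphan_group_size

    @property
    def probe_set_total(self) -> int:
        return self.good_sets + self.junction_sets + self.antisense_sets


@dataclass
class SimConfig:
    """Stated world for the simulator; the seed fully determines the output."""

    seed: int = 0
    n_genes: int = 12
    genome_length: int | None = None  # auto-sized when None
    transcripts_per_gene: tuple[int, int] = (2, 3)
    exons_per_transcript: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (120, 240)
    intron_length: tuple[int, int] = (80, 300)
    intergenic_gap: int = 400
    dropout: dict = field(
        default_factory=lambda: {"genbank": 0.4, "refseq": 0.6, "ensembl": 0.3}
    )
    planted: PlantedProbeCounts = field(default_factory=PlantedProbeCounts)
    # expression
    n_replicates: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    as_fold: float = 4.0
    noise_sigma: float = 0.1
    as_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass
class TruthSet:
    """Machine-readable ground truth for every planted quantity."""

    probe_class: dict[str, ProbeClass] = field(default_factory=dict)
    probe_set_count: int = 0
    gene_partition: dict[str, list[frozenset]] = field(default_factory=dict)
    as_genes: dict[str, float] = field(default_factory=dict)
    as_probe_set: dict[str, str] = field(default_factory=dict)

    def category_counts(self) -> Counter:
        return Counter(self.probe_class.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "probe_class": {p: c.value for p, c in sorted(self.probe_class.items())},
                "probe_set_count": self.probe_set_count,
                "gene_partition": {
                    m: [sorted(g) for g in sorted(parts, key=lambda s: sorted(s))]
                    for m, parts in self.gene_partition.items()
                },
                "as_genes": dict(sorted(self.as_genes.items())),
                "as_probe_set": dict(sorted(self.as_probe_set.items())),
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# Naive linkage oracle
# ---------------------------------------------------------------------------

def naive_cluster(collection: TranscriptCollection, method: LinkageMethod,
                  itbd_shared_intron: bool = False) -> list[frozenset[str]]:
    """Brute-force all-pairs + union-find clustering; the truth oracle for
    the optimized sweep in :func:`remapkit.gene_definition.cluster_transcripts`.
    """
    recs = sorted(collection, key=lambda r: r.transcript_id)
    parent = list(range(len(recs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if linked(recs[i], recs[j], method, itbd_shared_intron=itbd_shared_intron):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, set[str]] = {}
    for i, r in enumerate(recs):
        comps.setdefault(find(i), set()).add(r.transcript_id)
    return [frozenset(m) for m in comps.values()]


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------

@dataclass
class _GeneLayout:
    role: str
    strand: str
    exons: list[tuple[int, int]]  # scaffold exon coordinates (full transcript)
    tx_ids: list[str]
    span: tuple[int, int]
    cassette_index: int | None = None  # internal exon unique to the full transcript


@dataclass
class SimulatedAnnotation:
    genome: dict[str, str]
    collection: TranscriptCollection  # full multi-database union
    views: dict[str, TranscriptCollection]
    truth: TruthSet
    layout: dict = field(default_factory=dict)  # planting metadata (internal)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mk_record(tid: str, strand: str, exons: Sequence[tuple[int, int]],
               cds: tuple[int, int] | None = None) -> TranscriptRecord:
    exons = tuple(sorted(exons))
    tx_start, tx_end = exons[0][0], exons[-1][1]
    cs, ce = cds if cds else (tx_start, tx_start)
    return TranscriptRecord(
        transcript_id=tid,
        source_db=SourceDB.OTHER,
        chrom="chr1",
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exons=exons,
        cds_start=cs,
        cds_end=ce,
    )


def _standard_scaffold(rng: np.random.Generator, cursor: int, cfg: SimConfig,
                       gid: int, role: str, strand: str, n_tx: int,
                       first_exon_len: int | None = None,
                       drop_index: int | None = None) -> tuple[_GeneLayout, list[TranscriptRecord]]:
    elo, ehi = cfg.exons_per_transcript
    n_ex = int(rng.integers(max(elo, 3), ehi + 1)) if n_tx > 1 else int(rng.integers(elo, ehi + 1))
    n_tx = min(n_tx, n_ex - 1)  # need one distinct internal exon per variant
    lens = [int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1)) for _ in range(n_ex)]
    if first_exon_len:
        lens[0] = max(lens[0], first_exon_len)
    introns = [int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
               for _ in range(n_ex - 1)]
    exons: list[tuple[int, int]] = []
    pos = cursor
    for i, ln in enumerate(lens):
        exons.append((pos, pos + ln))
        pos += ln + (introns[i] if i < n_ex - 1 else 0)
    cds = (exons[0][0] + 15, exons[-1][1] - 15)
    tids = [f"t{gid:03d}{chr(ord('a') + k)}" for k in range(n_tx)]
    records = [_mk_record(tids[0], strand, exons, cds)]
    cassette = None
    for k in range(1, n_tx):
        d = drop_index if (drop_index is not None and k == 1) else ((k % (n_ex - 2)) + 1)
        if cassette is None:
            cassette = d
        records.append(_mk_record(tids[k], strand, [e for i, e in enumerate(exons) if i != d], cds))
    layout = _GeneLayout(
        role=role,
        strand=strand,
        exons=exons,
        tx_ids=tids,
        span=(exons[0][0], exons[-1][1]),
        cassette_index=cassette,
    )
    return layout, records


def simulate_annotation(config: SimConfig) -> SimulatedAnnotation:
    """Build the genome, the full transcript union, per-database views, and
    the truth gene partitions (naive linkage oracle, all four methods)."""
    rng = np.random.default_rng([int(config.seed) % (2**31), 1])
    p = config.planted

    roles: list[str] = []
    roles += ["good"] * max(p.good_sets, 1 if p.intronic else 0)
    roles += ["junction"] * p.junction_sets
    roles += ["orphan"] * p.orphan_groups
    if p.multi_gene:
        roles += ["antisense_a", "antisense_b"]
    if config.n_genes < len(roles):
        raise ValueError(
            f"infeasible config: n_genes={config.n_genes} < {len(roles)} required "
            "for the planted structures"
        )
    # structural extras that discriminate the linkage definitions; added
    # while the gene budget allows
    room = config.n_genes - len(roles)
    if room >= 2:
        roles += ["decoy_c", "decoy_d"]
        room -= 2
    for extra in ("single_exon", "itbd_split"):
        if room > 0:
            roles.append(extra)
            room -= 1
    roles += ["plain"] * room

    layouts: list[_GeneLayout] = []
    records: list[TranscriptRecord] = []
    cursor = 200
    gid = 0
    n_good_seen = 0
    for role in roles:
        gid += 1
        if role == "good":
            need = 8 + 26 * (p.probes_per_good_set
                             + (p.probes_per_antisense_set if n_good_seen == 0 else 0)) + 25
            lay, recs = _standard_scaffold(
                rng, cursor, config, gid, role,
                strand="+" if n_good_seen % 2 == 0 else "-",
                n_tx=int(rng.integers(config.transcripts_per_gene[0],
                                      config.transcripts_per_gene[1] + 1)),
                first_exon_len=need,
            )
            n_good_seen += 1
        elif role == "junction":
            lay, recs = _standard_scaffold(rng, cursor, config, gid, role, "+",
                                           n_tx=2, drop_index=1)
        elif role == "orphan":
            lay, recs = _standard_scaffold(rng, cursor, config, gid, role,
                                           strand="+" if gid % 2 else "-", n_tx=2)
        elif role == "antisense_a":
            exons = [(cursor, cursor + 250), (cursor + 370, cursor + 670)]
            lay = _GeneLayout(role, "+", exons, [f"t{gid:03d}a"], (cursor, cursor + 670))
            recs = [_mk_record(lay.tx_ids[0], "+", exons, (cursor + 20, cursor + 650))]
        elif role == "antisense_b":
            base = layouts[-1].span[0]  # antisense_a start
            exons = [(base + 500, base + 800), (base + 900, base + 1150)]
            lay = _GeneLayout(role, "-", exons, [f"t{gid:03d}a"], (base + 500, base + 1150))
            recs = [_mk_record(lay.tx_ids[0], "-", exons, (base + 520, base + 1130))]
            lay.span = (base + 500, base + 1150)
        elif role == "decoy_c":
            c = cursor
            exons = [(c, c + 200), (c + 300, c + 500), (c + 600, c + 1000)]
            lay = _GeneLayout(role, "+", exons, [f"t{gid:03d}a"], (c, c + 1000))
            recs = [_mk_record(lay.tx_ids[0], "+", exons, (c + 20, c + 450))]
        elif role == "decoy_d":
            c = layouts[-1].span[0]  # decoy_c start
            exons = [(c + 850, c + 980), (c + 1100, c + 1300), (c + 1400, c + 1600)]
            lay = _GeneLayout(role, "+", exons, [f"t{gid:03d}a"], (c + 850, c + 1600))
            recs = [_mk_record(lay.tx_ids[0], "+", exons, (c + 1150, c + 1550))]
        elif role == "single_exon":
            exons = [(cursor, cursor + 500)]
            lay = _GeneLayout(role, "+", exons, [f"t{gid:03d}a"], (cursor, cursor + 500))
            recs = [_mk_record(lay.tx_ids[0], "+", exons, (cursor + 30, cursor + 470))]
        elif role == "itbd_split":
            lay, recs = _standard_scaffold(rng, cursor, config, gid, role, "+", n_tx=1)
            # retained-intron variant: one exon spanning the first two scaffold
            # exons with offset boundaries -> ITBD/EXBD singleton
            ri_exon = (lay.exons[0][0] + 10, lay.exons[1][1] - 10)
            ri_id = f"t{gid:03d}z"
            recs.append(_mk_record(ri_id, "+", [ri_exon], (ri_exon[0] + 5, ri_exon[1] - 5)))
            lay.tx_ids.append(ri_id)
        else:  # plain
            lay, recs = _standard_scaffold(rng, cursor, config, gid, role,
                                           strand="+" if gid % 2 else "-",
                                           n_tx=config.transcripts_per_gene[0])
        if role != "antisense_b":  # antisense_b overlaps its partner by design
            pass
        layouts.append(lay)
        records.extend(recs)
        cursor = max(cursor, lay.span[1]) + config.intergenic_gap

    # intergenic tail with a duplicated block for MULTI_GENOME probes
    dup_len = max(25 + 30 * p.multi_genome, 100)
    dup_a = cursor + 100
    dup_b = dup_a + dup_len + 100
    total_len = dup_b + dup_len + 200
    if config.genome_length is not None:
        if config.genome_length < total_len:
            raise ValueError(
                f"infeasible config: layout needs {total_len} bases but "
                f"genome_length={config.genome_length}"
            )
        total_len = config.genome_length
    seq = list(_random_seq(rng, total_len))
    seq[dup_b : dup_b + dup_len] = seq[dup_a : dup_a + dup_len]
    genome = {"chr1": "".join(seq)}

    collection = TranscriptCollection(tuple(records), name="full")
    truth = TruthSet(
        gene_partition={
            m.value: naive_cluster(collection, m) for m in LinkageMethod
        }
    )

    views: dict[str, TranscriptCollection] = {}
    src_enum = {"genbank": SourceDB.GENBANK, "refseq": SourceDB.REFSEQ,
                "ensembl": SourceDB.ENSEMBL}
    for db, rate in config.dropout.items():
        keep = [r for r in records if rng.random() >= rate]
        src = src_enum.get(db, SourceDB.OTHER)
        views[db] = TranscriptCollection(
            tuple(replace(r, source_db=src) for r in keep), name=db
        )

    gaps: list[tuple[int, int]] = []
    prev_end = 0
    for lay in sorted(layouts, key=lambda l: l.span[0]):
        if lay.span[0] - prev_end > 150:
            gaps.append((prev_end + 50, lay.span[0] - 50))
        prev_end = max(prev_end, lay.span[1])

    return SimulatedAnnotation(
        genome=genome,
        collection=collection,
        views=views,
        truth=truth,
        layout={
            "genes": layouts,
            "gaps": gaps,
            "dup": (dup_a, dup_b, dup_len),
        },
    )


# ---------------------------------------------------------------------------
# Probe simulation
# ---------------------------------------------------------------------------

def _count_occurrences(genome: Mapping[str, str], seq: str) -> int:
    n = 0
    for needle in (seq, reverse_complement(seq)):
        for chrom_seq in genome.values():
            start = 0
            while True:
                i = chrom_seq.find(needle, start)
                if i < 0:
                    break
                n += 1
                start = i + 1
    return n


def simulate_probes(config: SimConfig,
                    annotation: SimulatedAnnotation) -> tuple[list[ProbeRecord], TruthSet]:
    """Plant probes with exact per-category counts; truth is by construction
    and verified against the genome (every planted genomic probe is unique,
    junction and random probes are absent)."""
    rng = np.random.default_rng([int(config.seed) % (2**31), 2])
    p = config.planted
    genome = annotation.genome
    chrom = "chr1"
    gseq = genome[chrom]
    truth = annotation.truth
    layouts: list[_GeneLayout] = annotation.layout["genes"]
    probes: list[ProbeRecord] = []

    def plant(pid: str, seq: str, cls: ProbeClass) -> None:
        probes.append(ProbeRecord(pid, seq))
        truth.probe_class[pid] = cls

    def sense_slice(start: int, strand: str) -> str:
        s = gseq[start : start + 25]
        return reverse_complement(s) if strand == "-" else s

    good_hosts = [l for l in layouts if l.role == "good"]
    # GOOD: constitutive-exon sets, one per host, in the (long) first exon
    for gi in range(p.good_sets):
        host = good_hosts[gi]
        e0 = host.exons[0]
        for j in range(p.probes_per_good_set):
            start = e0[0] + 4 + j * 26
            if start + 25 > e0[1]:
                raise ValueError("infeasible config: first exon too short for good set")
            plant(f"good_g{gi}_{j}", sense_slice(start, host.strand), ProbeClass.GOOD)

    # ANTISENSE sets on host 0, downstream of the sense probes
    if p.antisense_sets and good_hosts:
        host = good_hosts[0]
        e0 = host.exons[0]
        base = e0[0] + 4 + p.probes_per_good_set * 26
        for j in range(p.antisense_sets * p.probes_per_antisense_set):
            start = base + j * 26
            if start + 25 > e0[1]:
                raise ValueError("infeasible config: first exon too short for RC set")
            # reverse-complement of the transcript-sense sequence
            plant(f"rc_{j}", reverse_complement(sense_slice(start, host.strand)),
                  ProbeClass.GOOD)

    # JUNCTION: probes spanning the exon1-exon2 junction of the full
    # transcript (the cassette variant lacks exon1, so the signature is
    # the full transcript alone)
    for ji in range(p.junction_sets):
        host = next(l for l in layouts if l.role == "junction")
        e1, e2 = host.exons[1], host.exons[2]
        splits = [(13, 12), (10, 15), (16, 9), (8, 17), (18, 7), (11, 14), (14, 11)]
        if p.probes_per_junction_set > len(splits):
            raise ValueError("at most 7 probes per junction set supported")
        for j in range(p.probes_per_junction_set):
            left, right = splits[j]
            seq = gseq[e1[1] - left : e1[1]] + gseq[e2[0] : e2[0] + right]
            plant(f"jnc_{ji}_{j}", seq, ProbeClass.GOOD)

    # UNDERPOPULATED: small groups on the cassette exon unique to the full
    # transcript of each orphan host
    orphan_hosts = [l for l in layouts if l.role == "orphan"]
    for oi in range(p.orphan_groups):
        host = orphan_hosts[oi]
        ex = host.exons[host.cassette_index]
        for j in range(p.orphan_group_size):
            start = ex[0] + 4 + j * 26
            if start + 25 > ex[1]:
                raise ValueError("infeasible config: cassette exon too short")
            plant(f"orph_{oi}_{j}", sense_slice(start, host.strand),
                  ProbeClass.UNDERPOPULATED_SET)

    # MULTI_GENE: the antisense overlap region
    if p.multi_gene:
        a = next(l for l in layouts if l.role == "antisense_a")
        b = next(l for l in layouts if l.role == "antisense_b")
        lo = max(a.exons[-1][0], b.exons[0][0])
        hi = min(a.exons[-1][1], b.exons[0][1])
        for j in range(p.multi_gene):
            start = lo + 5 + j * 30
            if start + 25 > hi:
                raise ValueError("infeasible config: antisense overlap too short")
            plant(f"mgen_{j}", gseq[start : start + 25], ProbeClass.MULTI_GENE)

    # INTRONIC: middles of good-host introns (intronic in every variant:
    # the first intron region is intronic even when a later cassette exon
    # is dropped)
    slots = []
    for host in good_hosts:
        for i in range(len(host.exons) - 1):
            if host.cassette_index is not None and i + 1 == host.cassette_index:
                continue  # adjacent to the cassette exon; keep it simple
            intron = (host.exons[i][1], host.exons[i + 1][0])
            for k in range(2):
                start = intron[0] + 10 + k * 26
                if start + 25 <= intron[1] - 5:
                    slots.append(start)
    if p.intronic > len(slots):
        raise ValueError("infeasible config: not enough intron space")
    for j in range(p.intronic):
        plant(f"intr_{j}", gseq[slots[j] : slots[j] + 25], ProbeClass.INTRONIC)

    # INTERGENIC: gap middles
    gap_slots = []
    for lo, hi in annotation.layout["gaps"]:
        k = 0
        while lo + k * 30 + 25 <= hi:
            gap_slots.append(lo + k * 30)
            k += 1
    if p.intergenic > len(gap_slots):
        raise ValueError("infeasible config: not enough intergenic space")
    for j in range(p.intergenic):
        plant(f"intg_{j}", gseq[gap_slots[j] : gap_slots[j] + 25], ProbeClass.INTERGENIC)

    # MULTI_GENOME: the duplicated tail block
    dup_a, _, dup_len = annotation.layout["dup"]
    for j in range(p.multi_genome):
        start = dup_a + j * 30
        if j * 30 + 25 > dup_len:
            raise ValueError("infeasible config: duplicated block too short")
        plant(f"mgnm_{j}", gseq[start : start + 25], ProbeClass.MULTI_GENOME)

    # NO_GENOME: random 25-mers, verified absent below
    for j in range(p.no_genome):
        plant(f"nogn_{j}", _random_seq(rng, 25), ProbeClass.NO_GENOME)

    # --- construction verification -------------------------------------
    expected_hits = {
        ProbeClass.MULTI_GENOME: 2,
        ProbeClass.NO_GENOME: 0,
    }
    spliced_cache = [spliced_sequence(r, genome) for r in annotation.collection]
    for probe in probes:
        cls = truth.probe_class[probe.probe_id]
        n = _count_occurrences(genome, probe.sequence)
        want = 0 if probe.probe_id.startswith("jnc_") else expected_hits.get(cls, 1)
        if n != want:
            raise RuntimeError(
                f"planted probe {probe.probe_id} has {n} genome occurrences, expected {want}"
            )
        if want == 0 and cls is ProbeClass.NO_GENOME:
            for sp in spliced_cache:
                if probe.sequence in sp or reverse_complement(probe.sequence) in sp:
                    raise RuntimeError(
                        f"random probe {probe.probe_id} collides with a spliced sequence"
                    )

    truth.probe_set_count = p.probe_set_total
    return probes, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def skeleton_remapping(n_genes: int, sets_per_gene: int = 2, probes_per_set: int = 3,
                       seed: int = 0) -> RemappingResult:
    """A minimal synthetic RemappingResult (probe sets only) for driving
    expression simulation at scales where a full genome is unnecessary."""
    probe_sets = []
    probe_class: dict[str, ProbeClass] = {}
    probes: dict[str, ProbeRecord] = {}
    for g in range(n_genes):
        gid = f"g{g + 1:06d}"
        for s in range(sets_per_gene):
            pids = [f"{gid}_s{s}_p{k}" for k in range(probes_per_set)]
            for pid in pids:
                probe_class[pid] = ProbeClass.GOOD
                probes[pid] = ProbeRecord(pid, "A" * 25)
            probe_sets.append(
                ProbeSetDefinition(
                    probe_set_id=f"{gid}_{s + 1}",
                    gene_id=gid,
                    signature=frozenset({f"{gid}_t{s}"}),
                    sense=Sense.SENSE,
                    probe_ids=frozenset(pids),
                )
            )
    counts = {c: 0 for c in ProbeClass}
    counts[ProbeClass.GOOD] = len(probe_class)
    return RemappingResult(
        probe_class=probe_class,
        probe_sets=probe_sets,
        accounting=AccountingTable(counts=counts, probe_sets=len(probe_sets)),
        probes=probes,
    )


def simulate_expression(config: SimConfig,
                        remapping: RemappingResult) -> tuple[ExpressionMatrix, TruthSet]:
    """Two-condition expression for the remapping's probe sets with planted
    isoform switches.

    Baselines are log-normal per probe set; a planted AS gene has one probe
    set multiplied by ``as_fold`` in condition 2; replicates carry
    multiplicative log-normal noise exp(N(0, sigma^2)).
    """
    if config.noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng([int(config.seed) % (2**31), 3])
    by_gene = remapping.good_sets_by_gene()
    eligible = sorted(g for g, sets in by_gene.items() if len(sets) >= 2)
    n_as = int(round(config.as_fraction * len(eligible)))
    as_genes = list(rng.choice(eligible, size=n_as, replace=False)) if n_as else []

    truth = TruthSet()
    set_ids: list[str] = []
    base: list[float] = []
    fold2: list[float] = []
    for gene_id in sorted(by_gene):
        sets = sorted(by_gene[gene_id], key=lambda s: s.probe_set_id)
        is_as = gene_id in as_genes
        target = int(rng.integers(0, len(sets))) if is_as else -1
        if is_as:
            truth.as_genes[gene_id] = config.as_fold
            truth.as_probe_set[gene_id] = sets[target].probe_set_id
        for k, ps in enumerate(sets):
            set_ids.append(ps.probe_set_id)
            base.append(float(2.0 ** rng.normal(config.baseline_log2_mean,
                                                config.baseline_log2_sd)))
            fold2.append(config.as_fold if (is_as and k == target) else 1.0)

    base_arr = np.asarray(base)
    fold_arr = np.asarray(fold2)
    cols: dict[str, np.ndarray] = {}
    conditions: dict[str, str] = {}
    for cond_idx, cond in enumerate(("cond1", "cond2")):
        mean = base_arr * (fold_arr if cond_idx == 1 else 1.0)
        for r in range(config.n_replicates):
            sample = f"{cond}_r{r + 1}"
            noise = (
                np.exp(rng.normal(0.0, config.noise_sigma, size=len(base_arr)))
                if config.noise_sigma > 0
                else np.ones(len(base_arr))
            )
            cols[sample] = mean * noise
            conditions[sample] = cond
    values = pd.DataFrame(cols, index=set_ids)
    return ExpressionMatrix(values=values, conditions=conditions), truth
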