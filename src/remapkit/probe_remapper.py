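"""Probe classification and transcript-level probe-set regrouping.

Every 25-mer probe ends up in exactly one of seven mutually exclusive
categories, applied in a fixed precedence order:

1. ``MULTI_GENOME``       — two or more perfect genome matches.
2. ``NO_GENOME``          — no perfect match, even after junction rescue.
3. ``MULTI_GENE``         — unique placement, but its transcript signature
   spans two or more genes (e.g. overlapping UTRs, antisense overlap).
4. ``INTRONIC``           — empty signature, but inside some gene span.
5. ``INTERGENIC``         — empty signature, outside every gene span.
6. ``UNDERPOPULATED_SET`` — its candidate probe set has fewer than the
   minimum number of probes (default 3).
7. ``GOOD``               — survives all filters; member of a probe set.

Retained probes are grouped by (gene, transcript signature, sense): probes
interrogating exactly the same set of transcripts form one probe set.
Probes matching the reverse-complement strand of their transcripts are kept
in separate probe sets flagged ``_RC``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .annotation_io import AnnotationParseError, TranscriptCollection, TranscriptRecord
from .gene_definition import GeneModel

log = logging.getLogger(__name__)

PROBE_LENGTH = 25

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MatchType(str, enum.Enum):
    GENOMIC = "genomic"
    SPLICED = "spliced"


class Sense(str, enum.Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"


class ProbeClass(str, enum.Enum):
    MULTI_GENOME = "multi_genome"
    NO_GENOME = "no_genome"
    MULTI_GENE = "multi_gene"
    INTERGENIC = "intergenic"
    INTRONIC = "intronic"
    UNDERPOPULATED_SET = "underpopulated_set"
    GOOD = "good"


#: Accounting row labels, matching the published summary-table wording.
ACCOUNTING_LABELS: dict[ProbeClass, str] = {
    ProbeClass.MULTI_GENOME: "Probes with multiple alignments to the genome",
    ProbeClass.NO_GENOME: "Probes with no alignment to the genome",
    ProbeClass.MULTI_GENE: "Probes matching multiple genes",
    ProbeClass.INTERGENIC: "Probes matching intergenic region",
    ProbeClass.INTRONIC: "Probes matching intron region",
    ProbeClass.UNDERPOPULATED_SET: "< 3 probes per probe set",
    ProbeClass.GOOD: "Good probes",
}

PERCENTAGE_LABEL = "Percentage of good probes"
PROBE_SETS_LABEL = "Probe sets"


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    sequence: str
    original_probe_set: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError(
                f"{self.probe_id}: probe length {len(self.sequence)} != {PROBE_LENGTH}"
            )

    @property
    def is_valid_sequence(self) -> bool:
        return all(c in "ACGT" for c in self.sequence.upper())


@dataclass(frozen=True)
class ProbeGenomeHit:
    """One perfect-identity placement of a probe.

    For SPLICED hits ``transcripts`` names the spliced sequences matched and
    ``start`` is the genomic coordinate of the leftmost base covered.
    """

    probe_id: str
    chrom: str
    strand: str
    start: int
    end: int
    match_type: MatchType
    transcripts: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProbeSetDefinition:
    probe_set_id: str
    gene_id: str
    signature: frozenset[str]
    sense: Sense
    probe_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.signature:
            raise ValueError(f"{self.probe_set_id}: empty transcript signature")
        if not self.probe_ids:
            raise ValueError(f"{self.probe_set_id}: empty probe set")


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def good_probe_percentage(good: int, total: int) -> float:
    """Good-probe percentage, rounded to three decimals (e.g. 47.160)."""
    if total <= 0:
        return 0.0
    return round(100.0 * good / total, 3)


def summarize_category_counts(counts: Mapping[str, int], good_label: str = "Good probes") -> dict:
    """Total and good-probe percentage for any exhaustive category vector.

    Works for both the seven-row and the collapsed five-row (genome-issue and
    no-gene categories merged) table layouts.
    """
    if good_label not in counts:
        raise KeyError(f"no {good_label!r} entry in category counts")
    total = sum(counts.values())
    return {
        "total": total,
        "good": counts[good_label],
        "good_percentage": good_probe_percentage(counts[good_label], total),
    }


def probe_sets_per_gene(n_probe_sets: int, n_genes: int) -> float:
    """Average probe sets per gene covered, to three decimals; a proxy for
    the capacity to detect alternative splicing."""
    if n_genes <= 0:
        return 0.0
    return round(n_probe_sets / n_genes, 3)


def transcripts_per_probe_set(n_transcripts: int, n_probe_sets: int) -> float:
    """Average transcripts matched per probe set, to three decimals."""
    if n_probe_sets <= 0:
        return 0.0
    return round(n_transcripts / n_probe_sets, 3)


@dataclass(frozen=True)
class AccountingTable:
    counts: Mapping[ProbeClass, int]
    probe_sets: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def good_percentage(self) -> float:
        return good_probe_percentage(self.counts.get(ProbeClass.GOOD, 0), self.total)

    def rows(self) -> list[tuple[str, str]]:
        out = [(ACCOUNTING_LABELS[c], str(self.counts.get(c, 0))) for c in ProbeClass]
        out.append((PERCENTAGE_LABEL, f"{self.good_percentage:.3f}%"))
        out.append((PROBE_SETS_LABEL, str(self.probe_sets)))
        return out

    @classmethod
    def from_counts(cls, counts: Mapping[ProbeClass, int], probe_sets: int = 0) -> "AccountingTable":
        return cls(counts=dict(counts), probe_sets=probe_sets)


@dataclass
class RemappingResult:
    probe_class: dict[str, ProbeClass]
    probe_sets: list[ProbeSetDefinition]
    accounting: AccountingTable
    probes: dict[str, ProbeRecord]
    probe_location: dict[str, tuple[str, str, int]] = field(default_factory=dict)

    def good_sets_by_gene(self) -> dict[str, list[ProbeSetDefinition]]:
        out: dict[str, list[ProbeSetDefinition]] = {}
        for ps in self.probe_sets:
            out.setdefault(ps.gene_id, []).append(ps)
        return out


@dataclass(frozen=True)
class ComparisonTable:
    same: int
    diff: int
    unique_a: int
    unique_b: int


# ---------------------------------------------------------------------------
# Genome access
# ---------------------------------------------------------------------------

def as_genome(genome) -> Mapping[str, str]:
    """Normalize a genome source to a chrom -> uppercase-sequence mapping.

    Accepts a plain mapping of strings, a pyfaidx ``Fasta`` object, or a
    FASTA file path.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    if hasattr(genome, "keys"):
        return {k: str(genome[k][:]).upper() for k in genome.keys()}
    raise TypeError(f"cannot interpret genome source of type {type(genome)!r}")


def spliced_sequence(record: TranscriptRecord, genome: Mapping[str, str]) -> str:
    """Transcript (mRNA-sense) sequence assembled from its exons."""
    chrom_seq = genome[record.chrom]
    seq = "".join(chrom_seq[s:e] for s, e in record.exons)
    return reverse_complement(seq) if record.strand == "-" else seq


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_probes(probes: Sequence[ProbeRecord], genome) -> list[ProbeGenomeHit]:
    """Report every exact genome occurrence of each probe or its reverse
    complement; probes with non-ACGT characters are skipped with a warning.
    """
    chroms = as_genome(genome)
    fwd: dict[str, list[str]] = {}
    rev: dict[str, list[str]] = {}
    for p in probes:
        if not p.is_valid_sequence:
            log.warning("probe %s has non-ACGT characters; treated as unmatchable", p.probe_id)
            continue
        seq = p.sequence.upper()
        fwd.setdefault(seq, []).append(p.probe_id)
        rev.setdefault(reverse_complement(seq), []).append(p.probe_id)

    hits: list[ProbeGenomeHit] = []
    for chrom in sorted(chroms):
        seq = chroms[chrom]
        for i in range(len(seq) - PROBE_LENGTH + 1):
            window = seq[i : i + PROBE_LENGTH]
            for pid in fwd.get(window, ()):
                hits.append(
                    ProbeGenomeHit(pid, chrom, "+", i, i + PROBE_LENGTH, MatchType.GENOMIC)
                )
            for pid in rev.get(window, ()):
                hits.append(
                    ProbeGenomeHit(pid, chrom, "-", i, i + PROBE_LENGTH, MatchType.GENOMIC)
                )
    return hits


def _concat_to_genomic(record: TranscriptRecord, concat_pos: int) -> int:
    """Genomic coordinate of a position in the forward-ordered exon concat."""
    off = concat_pos
    for s, e in record.exons:
        if off < e - s:
            return s + off
        off -= e - s
    raise IndexError(f"{record.transcript_id}: concat position {concat_pos} out of range")


def rescue_junction_probes(
    unmatched: Sequence[ProbeRecord],
    transcripts: TranscriptCollection,
    genome,
) -> list[ProbeGenomeHit]:
    """Rescue genome-unmatched probes that span exon junctions.

    Each transcript's spliced sequence is assembled from its exons
    (reverse-complemented for minus-strand transcripts); probes with an
    exact 25-mer match in at least one spliced sequence get SPLICED hits
    naming those transcripts.
    """
    chroms = as_genome(genome)
    fwd: dict[str, list[str]] = {}
    rev: dict[str, list[str]] = {}
    for p in unmatched:
        if not p.is_valid_sequence:
            continue
        seq = p.sequence.upper()
        fwd.setdefault(seq, []).append(p.probe_id)
        rev.setdefault(reverse_complement(seq), []).append(p.probe_id)

    hits: list[ProbeGenomeHit] = []
    seen: set[tuple[str, str, str]] = set()  # collapse duplicate (probe, tx, strand)
    for record in transcripts:
        if record.chrom not in chroms:
            log.warning(
                "transcript %s references absent chromosome %s; skipped",
                record.transcript_id,
                record.chrom,
            )
            continue
        spliced = spliced_sequence(record, chroms)
        n = len(spliced)
        for i in range(n - PROBE_LENGTH + 1):
            window = spliced[i : i + PROBE_LENGTH]
            for pid_list, direct in ((fwd.get(window), True), (rev.get(window), False)):
                if not pid_list:
                    continue
                # probe matches transcript sense directly -> genomic strand is
                # the transcript's; reverse-complement match -> opposite
                if direct:
                    strand = record.strand
                else:
                    strand = "-" if record.strand == "+" else "+"
                concat_pos = i if record.strand == "+" else n - i - PROBE_LENGTH
                anchor = _concat_to_genomic(record, concat_pos)
                for pid in pid_list:
                    key = (pid, record.transcript_id, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    hits.append(
                        ProbeGenomeHit(
                            pid,
                            record.chrom,
                            strand,
                            anchor,
                            anchor + PROBE_LENGTH,
                            MatchType.SPLICED,
                            transcripts=(record.transcript_id,),
                        )
                    )
    return hits


# ---------------------------------------------------------------------------
# Signature assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureAssignment:
    signature: frozenset[str]
    gene_ids: frozenset[str]
    sense: Sense | None  # None when mixed across opposite-strand transcripts


class _ExonIndex:
    """Per-chromosome exon table for all-25-base containment queries."""

    def __init__(self, transcripts: TranscriptCollection) -> None:
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for r in transcripts:
            rows = self._by_chrom.setdefault(r.chrom, [])
            for s, e in r.exons:
                rows.append((s, e, r.transcript_id))
        for rows in self._by_chrom.values():
            rows.sort()

    def containing(self, chrom: str, start: int, end: int) -> set[str]:
        out: set[str] = set()
        for s, e, tid in self._by_chrom.get(chrom, ()):
            if s > start:
                break
            if end <= e:
                out.add(tid)
        return out


def _gene_of_transcripts(genes: Sequence[GeneModel]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for g in genes:
        for tid in g.transcript_ids:
            mapping[tid] = g.gene_id
    return mapping


def assign_signature(
    hit: ProbeGenomeHit,
    genes: Sequence[GeneModel],
    transcripts: TranscriptCollection,
    _exon_index: _ExonIndex | None = None,
    _gene_of: Mapping[str, str] | None = None,
) -> SignatureAssignment | None:
    """Transcript signature of a uniquely placed probe.

    GENOMIC hits: all transcripts whose exons fully contain the 25-base
    interval (partial exon overlap does not count). SPLICED hits: the
    transcripts named by the rescue. Returns None when no transcript is
    interrogated.
    """
    if hit.match_type is MatchType.GENOMIC:
        index = _exon_index or _ExonIndex(transcripts)
        signature = index.containing(hit.chrom, hit.start, hit.end)
    else:
        signature = set(hit.transcripts)
    if not signature:
        return None
    gene_of = _gene_of if _gene_of is not None else _gene_of_transcripts(genes)
    gene_ids = set()
    for tid in signature:
        if tid not in gene_of:
            raise ValueError(f"transcript {tid!r} not covered by any gene model")
        gene_ids.add(gene_of[tid])
    strands = {transcripts.get(t).strand for t in signature}
    sense: Sense | None
    if len(strands) > 1:
        sense = None
    else:
        sense = Sense.SENSE if hit.strand in strands else Sense.ANTISENSE
    return SignatureAssignment(frozenset(signature), frozenset(gene_ids), sense)


# ---------------------------------------------------------------------------
# Classification and grouping
# ---------------------------------------------------------------------------

def classify_and_group(
    probes: Sequence[ProbeRecord],
    hits: Sequence[ProbeGenomeHit],
    genes: Sequence[GeneModel],
    transcripts: TranscriptCollection,
    min_probes: int = 3,
    drop_antisense: bool = False,
) -> RemappingResult:
    """Classify every probe into one of the seven categories and group the
    survivors into transcript-signature probe sets.

    ``min_probes`` is the minimum probe-set size kept (sets with fewer
    members contribute their probes to UNDERPOPULATED_SET). With
    ``drop_antisense`` reverse-complement probe sets are filtered the same
    way instead of being retained as ``_RC`` sets.
    """
    probe_by_id = {p.probe_id: p for p in probes}
    if len(probe_by_id) != len(probes):
        raise ValueError("duplicate probe_ids in input")
    genomic: dict[str, list[ProbeGenomeHit]] = {}
    spliced: dict[str, list[ProbeGenomeHit]] = {}
    for h in hits:
        if h.probe_id not in probe_by_id:
            raise ValueError(f"hit references unknown probe {h.probe_id!r}")
        (genomic if h.match_type is MatchType.GENOMIC else spliced).setdefault(
            h.probe_id, []
        ).append(h)

    exon_index = _ExonIndex(transcripts)
    gene_of = _gene_of_transcripts(genes)
    gene_list = sorted(genes, key=lambda g: (g.chrom, g.span[0], g.span[1]))

    classification: dict[str, ProbeClass] = {}
    location: dict[str, tuple[str, str, int]] = {}
    # grouping key -> list of (anchor_start, probe_id)
    groups: dict[tuple[str, frozenset[str], Sense], list[tuple[int, str]]] = {}

    for p in probes:
        pid = p.probe_id
        ghits = genomic.get(pid, [])
        shits = spliced.get(pid, [])
        if len(ghits) >= 2:
            classification[pid] = ProbeClass.MULTI_GENOME
            continue
        if not ghits and not shits:
            classification[pid] = ProbeClass.NO_GENOME
            continue

        if ghits:
            hit = ghits[0]
            assignment = assign_signature(
                hit, gene_list, transcripts, _exon_index=exon_index, _gene_of=gene_of
            )
        else:
            # merge all spliced hits into one combined signature
            signature = {t for h in shits for t in h.transcripts}
            gene_ids = set()
            for tid in signature:
                if tid not in gene_of:
                    raise ValueError(f"transcript {tid!r} not covered by any gene model")
                gene_ids.add(gene_of[tid])
            strands = {transcripts.get(t).strand for t in signature}
            senses = {
                Sense.SENSE if h.strand == transcripts.get(t).strand else Sense.ANTISENSE
                for h in shits
                for t in h.transcripts
            }
            sense = senses.pop() if len(senses) == 1 and len(strands) == 1 else None
            assignment = SignatureAssignment(frozenset(signature), frozenset(gene_ids), sense)
            hit = min(shits, key=lambda h: (h.chrom, h.start))
        location[pid] = (hit.chrom, hit.strand, hit.start)

        if assignment is None:
            inside_span = any(
                g.chrom == hit.chrom and g.contains(hit.start, hit.end) for g in gene_list
            )
            classification[pid] = ProbeClass.INTRONIC if inside_span else ProbeClass.INTERGENIC
            continue
        if len(assignment.gene_ids) >= 2 or assignment.sense is None:
            classification[pid] = ProbeClass.MULTI_GENE
            continue
        gene_id = next(iter(assignment.gene_ids))
        groups.setdefault((gene_id, assignment.signature, assignment.sense), []).append(
            (hit.start, pid)
        )

    # probe-set formation
    kept: dict[tuple[str, frozenset[str], Sense], list[tuple[int, str]]] = {}
    for key, members in groups.items():
        _, _, sense = key
        if len(members) < min_probes or (drop_antisense and sense is Sense.ANTISENSE):
            for _, pid in members:
                classification[pid] = ProbeClass.UNDERPOPULATED_SET
        else:
            kept[key] = sorted(members)
            for _, pid in members:
                classification[pid] = ProbeClass.GOOD

    # deterministic naming: within each gene, number sets by the genomic
    # start of their leftmost probe; antisense sets get an _RC suffix
    by_gene: dict[str, list[tuple[int, frozenset[str], Sense]]] = {}
    for (gene_id, signature, sense), members in kept.items():
        by_gene.setdefault(gene_id, []).append((members[0][0], signature, sense))
    probe_sets: list[ProbeSetDefinition] = []
    for gene_id in sorted(by_gene):
        entries = sorted(
            by_gene[gene_id], key=lambda t: (t[0], sorted(t[1]), t[2].value)
        )
        for k, (_, signature, sense) in enumerate(entries, start=1):
            suffix = "_RC" if sense is Sense.ANTISENSE else ""
            probe_sets.append(
                ProbeSetDefinition(
                    probe_set_id=f"{gene_id}_{k}{suffix}",
                    gene_id=gene_id,
                    signature=signature,
                    sense=sense,
                    probe_ids=frozenset(pid for _, pid in kept[(gene_id, signature, sense)]),
                )
            )

    counts = {c: 0 for c in ProbeClass}
    for c in classification.values():
        counts[c] += 1
    accounting = AccountingTable(counts=counts, probe_sets=len(probe_sets))
    assert accounting.total == len(probes), "accounting must conserve the probe total"
    return RemappingResult(
        probe_class=classification,
        probe_sets=probe_sets,
        accounting=accounting,
        probes=probe_by_id,
        probe_location=location,
    )


# ---------------------------------------------------------------------------
# Remapping comparison
# ---------------------------------------------------------------------------

def compare_remappings(a: RemappingResult, b: RemappingResult) -> ComparisonTable:
    """Compare two remappings of the same probe universe gene-by-gene.

    Genes are paired when they share at least one GOOD probe. A 1-1 paired
    gene is Same iff its GOOD probes are partitioned into identical probe
    sets in both results (set labels ignored), else Diff. Genes with GOOD
    probes in only one result are UniqueA/UniqueB; many-to-many pairings
    count once as Diff.
    """
    if set(a.probe_class) != set(b.probe_class):
        raise ValueError("remappings were built from different probe universes")

    def gene_partitions(res: RemappingResult) -> dict[str, set[frozenset[str]]]:
        out: dict[str, set[frozenset[str]]] = {}
        for ps in res.probe_sets:
            out.setdefault(ps.gene_id, set()).add(ps.probe_ids)
        return out

    part_a, part_b = gene_partitions(a), gene_partitions(b)
    nodes = [("A", g) for g in part_a] + [("B", g) for g in part_b]
    node_idx = {n: i for i, n in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    probe_gene_b: dict[str, str] = {}
    for gid, sets in part_b.items():
        for s in sets:
            for pid in s:
                probe_gene_b[pid] = gid
    for gid, sets in part_a.items():
        for s in sets:
            for pid in s:
                if pid in probe_gene_b:
                    union(node_idx[("A", gid)], node_idx[("B", probe_gene_b[pid])])

    comps: dict[int, list[tuple[str, str]]] = {}
    for n, i in node_idx.items():
        comps.setdefault(find(i), []).append(n)

    same = diff = unique_a = unique_b = 0
    for members in comps.values():
        ga = [g for side, g in members if side == "A"]
        gb = [g for side, g in members if side == "B"]
        if not gb:
            unique_a += len(ga)
        elif not ga:
            unique_b += len(gb)
        elif len(ga) == 1 and len(gb) == 1:
            if part_a[ga[0]] == part_b[gb[0]]:
                same += 1
            else:
                diff += 1
        else:
            diff += 1
    return ComparisonTable(same=same, diff=diff, unique_a=unique_a, unique_b=unique_b)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def parse_probe_table(stream: Iterable[str] | IO[str]) -> list[ProbeRecord]:
    """TSV: probe_id, sequence[, original_probe_set]; '#' lines skipped."""
    probes: list[ProbeRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "probe_id":
            continue
        if len(parts) < 2:
            raise AnnotationParseError(f"line {lineno}: expected >=2 columns")
        probes.append(
            ProbeRecord(parts[0], parts[1], parts[2] if len(parts) > 2 and parts[2] else None)
        )
    return probes


def write_probeset_files(
    result: RemappingResult,
    definition: IO[str],
    accounting: IO[str],
    annotation: IO[str],
    header: str | None = None,
) -> None:
    """Emit the probe-set definition, accounting, and annotation TSVs."""

    def _hdr(stream: IO[str]) -> None:
        if header:
            for line in header.splitlines():
                stream.write(f"# {line}\n")

    _hdr(definition)
    definition.write(
        "probe_set_id\tgene_id\tsense\tsignature\tprobe_id\tsequence\tchrom\tstrand\tstart\n"
    )
    for ps in sorted(result.probe_sets, key=lambda s: s.probe_set_id):
        sig = ";".join(sorted(ps.signature))
        for pid in sorted(ps.probe_ids):
            chrom, strand, start = result.probe_location.get(pid, ("NA", "NA", -1))
            definition.write(
                f"{ps.probe_set_id}\t{ps.gene_id}\t{ps.sense.value}\t{sig}\t{pid}\t"
                f"{result.probes[pid].sequence}\t{chrom}\t{strand}\t{start}\n"
            )

    _hdr(accounting)
    for label, value in result.accounting.rows():
        accounting.write(f"{label}\t{value}\n")

    _hdr(annotation)
    annotation.write("probe_set_id\tgene_id\tsense\tn_probes\tsignature\tchrom\tstart\tend\n")
    for ps in sorted(result.probe_sets, key=lambda s: s.probe_set_id):
        locs = [result.probe_location[p] for p in ps.probe_ids if p in result.probe_location]
        chrom = locs[0][0] if locs else "NA"
        start = min(l[2] for l in locs) if locs else -1
        end = max(l[2] for l in locs) + PROBE_LENGTH if locs else -1
        annotation.write(
            f"{ps.probe_set_id}\t{ps.gene_id}\t{ps.sense.value}\t{len(ps.probe_ids)}\t"
            + ";".join(sorted(ps.signature))
            + f"\t{chrom}\t{start}\t{end}\n"
        )


def read_probeset_definitions(stream: Iterable[str] | IO[str]) -> list[ProbeSetDefinition]:
    """Re-read a probe-set definition TSV into ProbeSetDefinition objects."""
    rows: dict[str, dict] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("probe_set_id\t"):
            continue
        ps_id, gene_id, sense, sig, pid = line.split("\t")[:5]
        entry = rows.setdefault(
            ps_id,
            {
                "gene_id": gene_id,
                "sense": Sense(sense),
                "signature": frozenset(sig.split(";")),
                "probe_ids": set(),
            },
        )
        entry["probe_ids"].add(pid)
    return [
        ProbeSetDefinition(
            probe_set_id=ps_id,
            gene_id=e["gene_id"],
            signature=e["signature"],
            sense=e["sense"],
            probe_ids=frozenset(e["probe_ids"]),
        )
        for ps_id, e in sorted(rows.items())
    ]
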