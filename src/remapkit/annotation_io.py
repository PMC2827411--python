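"""Transcript annotation I/O: genePred and PSL parsing, alignment filtering,
cross-reference tables, and multi-database integration.

All coordinates are 0-based half-open throughout (genePred/PSL native).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Mapping

log = logging.getLogger(__name__)


class SourceDB(str, enum.Enum):
    """Origin database of a transcript record."""

    GENBANK = "genbank"
    REFSEQ = "refseq"
    ENSEMBL = "ensembl"
    OTHER = "other"


class AnnotationParseError(ValueError):
    """Raised for malformed genePred/PSL/xref input; message names the line."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript's exon/CDS structure on the genome.

    ``cds_start == cds_end`` encodes a non-coding transcript. Exons are
    half-open ``(start, end)`` intervals, pairwise disjoint and sorted.
    """

    transcript_id: str
    source_db: SourceDB
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if self.tx_start > self.exons[0][0] or self.exons[-1][1] > self.tx_end:
            raise ValueError(f"{self.transcript_id}: exons outside tx bounds")
        if self.cds_start > self.cds_end:
            raise ValueError(f"{self.transcript_id}: cds_start > cds_end")
        if self.cds_start != self.cds_end and not (
            self.tx_start <= self.cds_start and self.cds_end <= self.tx_end
        ):
            raise ValueError(f"{self.transcript_id}: CDS outside tx bounds")

    @property
    def is_coding(self) -> bool:
        return self.cds_start != self.cds_end

    @property
    def cds_exons(self) -> tuple[tuple[int, int], ...]:
        """Exon intervals clipped to the CDS; empty for non-coding records."""
        if not self.is_coding:
            return ()
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return tuple(out)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def intron_boundaries(self) -> frozenset[tuple[str, int]]:
        """Typed splice-site coordinates: ("L", intron start) and
        ("R", intron end) per intron.

        Sides are genome-oriented; a left edge never matches a right edge at
        the same coordinate (they are distinct splice sites), which also
        guarantees that transcripts sharing a boundary overlap in exons.
        """
        coords: set[tuple[str, int]] = set()
        for s, e in self.introns:
            coords.add(("L", s))
            coords.add(("R", e))
        return frozenset(coords)


@dataclass(frozen=True)
class TranscriptAlignment:
    """A single placement of a transcript on the genome with its identity."""

    transcript_id: str
    source_db: SourceDB
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    blocks: tuple[tuple[int, int], ...]
    base_identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_identity <= 1.0:
            raise ValueError(
                f"{self.transcript_id}: base_identity {self.base_identity} not in [0,1]"
            )


@dataclass
class TranscriptCollection:
    """A named set of TranscriptRecords with unique transcript_ids."""

    records: tuple[TranscriptRecord, ...]
    name: str = "collection"
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        self._by_id = {r.transcript_id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            seen: set[str] = set()
            for r in self.records:
                if r.transcript_id in seen:
                    raise ValueError(f"duplicate transcript_id {r.transcript_id!r}")
                seen.add(r.transcript_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self.records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def get(self, transcript_id: str) -> TranscriptRecord:
        return self._by_id[transcript_id]

    def validate_against_genome(self, chrom_lengths: Mapping[str, int]) -> None:
        """Check every record's chromosome exists and fits the genome."""
        for r in self.records:
            if r.chrom not in chrom_lengths:
                raise ValueError(f"{r.transcript_id}: unknown chromosome {r.chrom!r}")
            if r.tx_end > chrom_lengths[r.chrom]:
                raise ValueError(f"{r.transcript_id}: extends past end of {r.chrom}")


# ---------------------------------------------------------------------------
# genePred
# ---------------------------------------------------------------------------

def parse_genepred(stream: Iterable[str] | IO[str], source_db: SourceDB = SourceDB.OTHER,
                   name: str | None = None) -> TranscriptCollection:
    """Parse tab-separated genePred (10 or 15+ fields per line).

    Comment lines starting with ``#`` and blank lines are skipped. Trailing
    commas in the exonStarts/exonEnds lists are tolerated. Malformed lines
    raise :class:`AnnotationParseError` naming the line number.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 10:
            raise AnnotationParseError(
                f"line {lineno}: expected >=10 genePred fields, got {len(fields)}"
            )
        tid, chrom, strand = fields[0], fields[1], fields[2]
        try:
            tx_start, tx_end = int(fields[3]), int(fields[4])
            cds_start, cds_end = int(fields[5]), int(fields[6])
            exon_count = int(fields[7])
            starts = [int(x) for x in fields[8].rstrip(",").split(",")]
            ends = [int(x) for x in fields[9].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: malformed coordinate ({exc})") from None
        if len(starts) != exon_count or len(ends) != exon_count:
            raise AnnotationParseError(
                f"line {lineno}: exonCount={exon_count} but "
                f"{len(starts)} starts / {len(ends)} ends"
            )
        if tid in seen:
            raise AnnotationParseError(f"line {lineno}: duplicate transcript_id {tid!r}")
        seen.add(tid)
        try:
            records.append(
                TranscriptRecord(
                    transcript_id=tid,
                    source_db=source_db,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=tuple(zip(starts, ends)),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: {exc}") from None
    return TranscriptCollection(tuple(records), name=name or source_db.value)


def write_genepred(collection: TranscriptCollection, stream: IO[str],
                   header: str | None = None) -> None:
    """Serialize a collection as 10-field genePred (0-based half-open)."""
    if header:
        for line in header.splitlines():
            stream.write(f"# {line}\n")
    for r in collection:
        starts = ",".join(str(s) for s, _ in r.exons) + ","
        ends = ",".join(str(e) for _, e in r.exons) + ","
        stream.write(
            "\t".join(
                [
                    r.transcript_id,
                    r.chrom,
                    r.strand,
                    str(r.tx_start),
                    str(r.tx_end),
                    str(r.cds_start),
                    str(r.cds_end),
                    str(len(r.exons)),
                    starts,
                    ends,
                ]
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

#: matches / (matches + misMatches + repMatches); insertions excluded.
PSL_IDENTITY_CONVENTION = "matches/(matches+misMatches+repMatches)"


def parse_psl(stream: Iterable[str] | IO[str],
              source_db: SourceDB = SourceDB.OTHER) -> list[TranscriptAlignment]:
    """Parse 21-column PSL alignments; optional psLayout header skipped.

    Base identity uses :data:`PSL_IDENTITY_CONVENTION`.
    """
    alignments: list[TranscriptAlignment] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            continue
        # psLayout header block: title, column names (2 lines), dashes
        if (
            stripped.startswith("psLayout")
            or stripped.startswith("-")
            or stripped.startswith("match\t")
            or stripped.startswith("match ")
            or stripped.split("\t")[0] in ("", "match")
        ):
            continue
        fields = line.split("\t")
        if len(fields) != 21:
            raise AnnotationParseError(
                f"line {lineno}: expected 21 PSL columns, got {len(fields)}"
            )
        try:
            matches, mismatches, rep_matches = (int(fields[i]) for i in range(3))
            strand = fields[8]
            qname = fields[9]
            tname = fields[13]
            tstart, tend = int(fields[15]), int(fields[16])
            block_count = int(fields[17])
            sizes = [int(x) for x in fields[18].rstrip(",").split(",")]
            tstarts = [int(x) for x in fields[20].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: malformed PSL field ({exc})") from None
        if len(sizes) != block_count or len(tstarts) != block_count:
            raise AnnotationParseError(f"line {lineno}: block count mismatch")
        denom = matches + mismatches + rep_matches
        identity = matches / denom if denom else 0.0
        # merge abutting target blocks; PSL blocks may abut without an intron
        blocks: list[tuple[int, int]] = []
        for ts, sz in zip(tstarts, sizes):
            if blocks and ts <= blocks[-1][1]:
                blocks[-1] = (blocks[-1][0], max(blocks[-1][1], ts + sz))
            else:
                blocks.append((ts, ts + sz))
        alignments.append(
            TranscriptAlignment(
                transcript_id=qname,
                source_db=source_db,
                chrom=tname,
                strand=strand[0] if strand else "+",
                tx_start=tstart,
                tx_end=tend,
                blocks=tuple(blocks),
                base_identity=identity,
            )
        )
    return alignments


# ---------------------------------------------------------------------------
# Alignment filtering
# ---------------------------------------------------------------------------

#: Near-best retention windows in identity fraction, per source database.
DEFAULT_NEAR_BEST_WINDOW: dict[SourceDB, float] = {
    SourceDB.REFSEQ: 0.001,
    SourceDB.GENBANK: 0.005,
    SourceDB.ENSEMBL: 0.0,
    SourceDB.OTHER: 0.0,
}


def filter_transcript_alignments(
    alignments: list[TranscriptAlignment],
    min_identity: float = 0.96,
    near_best_window: Mapping[SourceDB, float] | None = None,
    cds: Mapping[str, tuple[int, int]] | None = None,
    name: str = "filtered",
) -> TranscriptCollection:
    """Keep placements with identity >= ``min_identity``; for multi-placement
    transcripts keep those within the per-source near-best window of the best.

    ``cds`` optionally supplies genomic CDS intervals per transcript_id;
    placements without one are recorded as non-coding. Multi-placement
    survivors get ``@2``, ``@3`` ... suffixes to keep IDs unique.
    """
    windows = dict(DEFAULT_NEAR_BEST_WINDOW)
    if near_best_window:
        windows.update(near_best_window)
    passing = [a for a in alignments if a.base_identity >= min_identity]
    by_tid: dict[str, list[TranscriptAlignment]] = {}
    for a in passing:
        by_tid.setdefault(a.transcript_id, []).append(a)

    records: list[TranscriptRecord] = []
    for tid in sorted(by_tid):
        placements = by_tid[tid]
        best = max(p.base_identity for p in placements)
        src = placements[0].source_db
        if src not in windows:
            raise ValueError(f"no near-best window configured for source {src!r}")
        kept = [p for p in placements if p.base_identity >= best - windows[src]]
        kept.sort(key=lambda p: (-p.base_identity, p.chrom, p.tx_start))
        for i, p in enumerate(kept):
            rid = tid if i == 0 else f"{tid}@{i + 1}"
            cds_iv = (cds or {}).get(tid)
            cs, ce = cds_iv if cds_iv else (p.tx_start, p.tx_start)
            records.append(
                TranscriptRecord(
                    transcript_id=rid,
                    source_db=p.source_db,
                    chrom=p.chrom,
                    strand=p.strand,
                    tx_start=p.tx_start,
                    tx_end=p.tx_end,
                    exons=p.blocks,
                    cds_start=cs,
                    cds_end=ce,
                )
            )
    return TranscriptCollection(tuple(records), name=name)


# ---------------------------------------------------------------------------
# Cross-reference tables and integration
# ---------------------------------------------------------------------------

def parse_xref(stream: Iterable[str] | IO[str]) -> dict[str, str]:
    """Parse a two-column TSV mapping transcript_id -> gene_id."""
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise AnnotationParseError(f"line {lineno}: expected 2 columns")
        tid, gid = parts[0], parts[1]
        if tid in mapping and mapping[tid] != gid:
            raise AnnotationParseError(
                f"line {lineno}: transcript {tid!r} maps to multiple gene IDs"
            )
        mapping[tid] = gid
    return mapping


def integrate_collections(collections: list[TranscriptCollection],
                          name: str = "integrated") -> TranscriptCollection:
    """Union of collections; colliding transcript_ids are source-prefixed.

    Every member of a colliding ID group is retained under a
    ``{source}:{id}`` (or ``{collection name}:{id}`` on same-source clashes)
    prefix. Per-source counts are recorded in ``provenance``.
    """
    id_count: dict[str, int] = {}
    for coll in collections:
        for r in coll:
            id_count[r.transcript_id] = id_count.get(r.transcript_id, 0) + 1

    records: list[TranscriptRecord] = []
    used: set[str] = set()
    provenance: dict[str, str] = {}
    for coll in collections:
        n = 0
        for r in coll:
            rid = r.transcript_id
            if id_count[rid] > 1:
                rid = f"{r.source_db.value}:{rid}"
            if rid in used:
                rid = f"{coll.name}:{r.transcript_id}"
            k = 2
            base = rid
            while rid in used:
                rid = f"{base}#{k}"
                k += 1
            used.add(rid)
            records.append(replace(r, transcript_id=rid) if rid != r.transcript_id else r)
            n += 1
        provenance[coll.name] = str(n)
    return TranscriptCollection(tuple(records), name=name, provenance=provenance)
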