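"""Gene-model data types, GTF/FASTA/BED I/O and genomic-context computations.

Internal coordinates are 0-based half-open throughout; GTF I/O converts to and
from the format's 1-based inclusive convention.  A splice junction is carried
as its intron interval ``(start, end)`` in genomic coordinates: ``start`` is
the first intronic base, ``end`` one past the last.  On the ``+`` strand the
donor coordinate equals the intron start (the 3' boundary of the upstream
exon) and the acceptor equals the intron end; on ``-`` the roles swap.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import gffutils

__all__ = [
    "AnnotationError",
    "Exon",
    "Transcript",
    "Gene",
    "GenomeAnnotation",
    "IntergenicDistance",
    "load_annotation",
    "write_annotation",
    "consecutive_gene_pairs",
    "intergenic_distance",
    "intron_lengths",
    "annotate_position_region",
    "domain_overlap_proportion",
    "read_fasta",
    "write_fasta",
    "donor_acceptor_to_intron",
    "intron_to_donor_acceptor",
]

REGION_LABELS = ("5'UTR", "CDS", "3'UTR", "intron", "non-coding exon", "intergenic")


class AnnotationError(ValueError):
    """Raised for malformed gene models or inconsistent coordinates."""


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(f"exon start must precede end: {self}")
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -: {self}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """Exons are kept in transcription (5'->3') order."""

    id: str
    gene_id: str
    exons: list[Exon]
    cds_start: int | None = None  # genomic, 0-based half-open bounds
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.id} has no exons")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.id}: overlapping exons {a} and {b}"
                )
        # transcription order: genomic order on +, reversed on -
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (genomic, half-open) in transcription order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a.end, b.start) if self.strand == "+" else (b.end, a.start)
            out.append((lo, hi))
        return out


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts.values())

    def longest_transcript(self) -> Transcript:
        """Deterministic reference transcript: most exonic bp, ties by id."""
        return max(
            self.transcripts.values(),
            key=lambda t: (sum(len(e) for e in t.exons), t.id),
        )

    def junctions(self) -> set[tuple[int, int]]:
        """All annotated intron intervals over every transcript."""
        out: set[tuple[int, int]] = set()
        for t in self.transcripts.values():
            out.update(t.introns())
        return out

    def exon_boundaries(self) -> tuple[set[int], set[int]]:
        """(donor boundaries, acceptor boundaries) as genomic coordinates.

        Donor boundaries are 3'-ends of exons in transcription orientation,
        acceptor boundaries 5'-starts; expressed in the half-open convention a
        ``+``-strand donor is an ``exon.end``, a ``-``-strand donor an
        ``exon.start``.
        """
        donors: set[int] = set()
        acceptors: set[int] = set()
        for t in self.transcripts.values():
            for e in t.exons:
                if self.strand == "+":
                    donors.add(e.end)
                    acceptors.add(e.start)
                else:
                    donors.add(e.start)
                    acceptors.add(e.end)
        return donors, acceptors


class IntergenicDistance(NamedTuple):
    distance: int
    overlap: bool


@dataclass
class GenomeAnnotation:
    """Genes plus the auxiliary registries used across the pipeline."""

    genes: dict[str, Gene] = field(default_factory=dict)
    polya_sites: dict[str, list[int]] = field(default_factory=dict)
    domains: list[tuple[str, int, int, str]] = field(default_factory=list)

    def validate(self) -> None:
        for g in self.genes.values():
            for t in g.transcripts.values():
                for e in t.exons:
                    if e.start < g.start or e.end > g.end:
                        raise AnnotationError(
                            f"exon {e} of transcript {t.id} outside gene {g.id} span"
                        )

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes.values() if g.chrom == chrom),
            key=lambda g: (g.start, g.end, g.id),
        )

    def chromosomes(self) -> list[str]:
        return sorted({g.chrom for g in self.genes.values()})

    def genes_containing(
        self, chrom: str, pos: int, strand: str | None = None
    ) -> list[Gene]:
        out = [
            g
            for g in self.genes.values()
            if g.chrom == chrom and g.start <= pos <= g.end
        ]
        if strand is not None:
            out = [g for g in out if g.strand == strand]
        return sorted(out, key=lambda g: g.id)

    def is_encapsulated(self, inner: Gene, outer: Gene) -> bool:
        """Gene span fully contained in another gene's span, either strand."""
        return (
            inner.id != outer.id
            and inner.chrom == outer.chrom
            and outer.start <= inner.start
            and inner.end <= outer.end
        )


def donor_acceptor_to_intron(donor: int, acceptor: int, strand: str) -> tuple[int, int]:
    return (donor, acceptor) if strand == "+" else (acceptor, donor)


def intron_to_donor_acceptor(start: int, end: int, strand: str) -> tuple[int, int]:
    return (start, end) if strand == "+" else (end, start)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def write_annotation(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write genes/transcripts/exons/CDS as GTF (1-based inclusive)."""
    lines = []
    for gid in sorted(ann.genes):
        g = ann.genes[gid]

        def row(feature: str, start: int, end: int, attrs: str) -> str:
            return (
                f"{g.chrom}\tcgsplice\t{feature}\t{start + 1}\t{end}\t.\t"
                f"{g.strand}\t.\t{attrs}"
            )

        lines.append(row("gene", g.start, g.end, f'gene_id "{gid}";'))
        for tid in sorted(g.transcripts):
            t = g.transcripts[tid]
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            lines.append(row("transcript", t.start, t.end, attrs))
            for e in sorted(t.exons, key=lambda e: e.start):
                lines.append(row("exon", e.start, e.end, attrs))
            if t.is_coding:
                lines.append(row("CDS", t.cds_start, t.cds_end, attrs))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_annotation(path: str | os.PathLike) -> GenomeAnnotation:
    """Parse a GTF file into a :class:`GenomeAnnotation`.

    Coordinates are converted from GTF 1-based inclusive to the internal
    0-based half-open convention.  Overlapping exons within a transcript or
    exons outside their gene span raise :class:`AnnotationError` naming the
    offending record.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    ann = GenomeAnnotation()
    for f in db.features_of_type("gene"):
        gid = f.attributes["gene_id"][0]
        ann.genes[gid] = Gene(id=gid, chrom=f.seqid, strand=f.strand)
    tx_gene: dict[str, str] = {}
    tx_exons: dict[str, list[Exon]] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    for f in db.features_of_type("transcript"):
        tid = f.attributes["transcript_id"][0]
        tx_gene[tid] = f.attributes["gene_id"][0]
        tx_exons[tid] = []
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        tx_exons.setdefault(tid, [])
        tx_gene.setdefault(tid, f.attributes["gene_id"][0])
        tx_exons[tid].append(Exon(f.seqid, f.start - 1, f.end, f.strand))
    for f in db.features_of_type("CDS"):
        tid = f.attributes["transcript_id"][0]
        tx_cds.setdefault(tid, []).append((f.start - 1, f.end))
    for tid, exons in tx_exons.items():
        gid = tx_gene[tid]
        if gid not in ann.genes:
            raise AnnotationError(f"transcript {tid} references unknown gene {gid}")
        try:
            t = Transcript(id=tid, gene_id=gid, exons=exons)
        except AnnotationError as err:
            raise AnnotationError(f"while parsing transcript {tid}: {err}") from err
        if tid in tx_cds:
            t.cds_start = min(s for s, _ in tx_cds[tid])
            t.cds_end = max(e for _, e in tx_cds[tid])
        ann.genes[gid].transcripts[tid] = t
    # gene span is defined by the GTF gene rows; cross-check exon containment
    for f in db.features_of_type("gene"):
        gid = f.attributes["gene_id"][0]
        g = ann.genes[gid]
        for t in g.transcripts.values():
            for e in t.exons:
                if e.start < f.start - 1 or e.end > f.end:
                    raise AnnotationError(
                        f"exon {e.start}-{e.end} of transcript {t.id} lies outside "
                        f"the span of gene {gid}"
                    )
    empty = [gid for gid, g in ann.genes.items() if not g.transcripts]
    for gid in empty:  # tolerate annotation-only genes (e.g., miRNA stubs)...
        del ann.genes[gid]
    return ann


# ---------------------------------------------------------------------------
# FASTA / BED I/O
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    out = {name: str(fa[name][:]) for name in fa.keys()}
    try:
        os.remove(str(path) + ".fai")
    except OSError:
        pass
    return out


def write_bed(intervals: Iterable[tuple], path: str | os.PathLike) -> None:
    """Write BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | os.PathLike) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, n, sc, st = line.rstrip("\n").split("\t")
            out.append((c, int(s), int(e), n, sc, st))
    return out


# ---------------------------------------------------------------------------
# Genomic-context operations
# ---------------------------------------------------------------------------

def consecutive_gene_pairs(
    ann: GenomeAnnotation, same_strand_only: bool = False
) -> list[tuple[Gene, Gene]]:
    """Adjacent gene pairs ordered by genomic start per chromosome.

    Adjacency is defined over all genes regardless of strand — the background
    set of "consecutive gene distances" spans the whole genome — and the
    ``same_strand_only`` flag then restricts to co-oriented neighbours, as
    required for conjoined-gene candidacy.  Genes encapsulated within another
    gene (e.g., an intronic miRNA) never participate in pairing.
    """
    pairs: list[tuple[Gene, Gene]] = []
    for chrom in ann.chromosomes():
        genes = ann.genes_on(chrom)
        genes = [
            g
            for g in genes
            if not any(ann.is_encapsulated(g, other) for other in genes)
        ]
        for a, b in zip(genes, genes[1:]):
            if same_strand_only and a.strand != b.strand:
                continue
            pairs.append((a, b))
    return pairs


def intergenic_distance(upstream: Gene, downstream: Gene) -> IntergenicDistance:
    """Gap in bp between an upstream gene's end and a downstream gene's start.

    Overlapping or abutting genes yield distance 0; overlap is flagged rather
    than reported as a negative distance.
    """
    if upstream.chrom != downstream.chrom:
        raise AnnotationError(
            f"genes {upstream.id} and {downstream.id} are on different chromosomes"
        )
    first, second = (
        (upstream, downstream)
        if upstream.start <= downstream.start
        else (downstream, upstream)
    )
    gap = second.start - first.end
    if gap < 0:
        return IntergenicDistance(0, True)
    return IntergenicDistance(gap, False)


def intron_lengths(transcript: Transcript) -> list[int]:
    """Lengths of the gaps between consecutive exons in transcription order."""
    return [hi - lo for lo, hi in transcript.introns()]


def annotate_position_region(
    gene: Gene, position: int, flank: int = 10_000
) -> str:
    """Classify a genomic position relative to a gene's reference transcript.

    Returns one of ``5'UTR``, ``CDS``, ``3'UTR``, ``intron``,
    ``non-coding exon`` or ``intergenic``.  Exonic labels take precedence over
    ``intron``; coding sub-classification requires annotated CDS bounds.  The
    reference transcript is the gene's longest (deterministic) transcript.
    """
    if position < gene.start - flank or position > gene.end + flank:
        raise AnnotationError(
            f"position {position} outside gene {gene.id} span +/- {flank}"
        )
    t = gene.longest_transcript()
    if position < t.start or position >= t.end:
        return "intergenic"
    in_exon = any(e.start <= position < e.end for e in t.exons)
    if not in_exon:
        return "intron"
    if not t.is_coding:
        return "non-coding exon"
    if t.cds_start <= position < t.cds_end:
        return "CDS"
    before_cds = position < t.cds_start
    # 5'UTR lies before the CDS in transcription orientation
    if gene.strand == "+":
        return "5'UTR" if before_cds else "3'UTR"
    return "3'UTR" if before_cds else "5'UTR"


def domain_overlap_proportion(
    events: Sequence[tuple[str, int, int]],
    domains: Sequence[tuple[str, int, int]] | Sequence[tuple[str, int, int, str]],
) -> float:
    """Fraction of event intervals overlapping >= 1 domain interval by >= 1 bp."""
    if len(events) == 0:
        raise AnnotationError("empty event list")
    doms = [(d[0], d[1], d[2]) for d in domains]
    n_hit = 0
    for chrom, start, end in events:
        for dc, ds, de in doms:
            if dc == chrom and start < de and ds < end:
                n_hit += 1
                break
    return n_hit / len(events)
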