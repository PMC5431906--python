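"""Long-read filtering, gene mapping, CG discovery and validation.

Long reads are represented as ordered splice-junction chains (intron
intervals in genomic coordinates) with alignment-quality attributes.  Reads
with aligned proportion < 0.90 or sequence identity < 0.80 are discarded.  A
read maps to a gene when at least three of its junctions exactly match that
gene's annotated junctions; reads mapping across exactly two co-oriented,
non-encapsulated genes nominate a CG candidate.  A short-read CG call is
validated by a read containing a junction whose coordinates equal the call's
donor/acceptor exactly (a tolerance window exists but defaults to 0 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotations import GenomeAnnotation, intron_to_donor_acceptor

__all__ = [
    "LongRead",
    "filter_long_reads",
    "map_read_to_genes",
    "detect_cg_long",
    "validate_cg",
    "read_longread_table",
    "write_longread_table",
]

MIN_ALIGNED_PROPORTION = 0.90
MIN_IDENTITY = 0.80
MIN_JUNCTIONS_PER_GENE = 3


@dataclass
class LongRead:
    id: str
    chrom: str
    strand: str
    junctions: list[tuple[int, int]]  # intron intervals, genomic order
    aligned_proportion: float
    identity: float

    def __post_init__(self) -> None:
        self.junctions = sorted(tuple(j) for j in self.junctions)
        for (a0, a1), (b0, b1) in zip(self.junctions, self.junctions[1:]):
            if b0 < a1:
                raise ValueError(f"read {self.id}: overlapping junctions")


@dataclass
class CGCandidate:
    upstream_gene: str
    downstream_gene: str
    chrom: str
    strand: str
    donor: int
    acceptor: int
    read_id: str


def filter_long_reads(reads) -> list[LongRead]:
    """Keep reads with aligned proportion >= 0.90 and identity >= 0.80."""
    return [
        r
        for r in reads
        if r.aligned_proportion >= MIN_ALIGNED_PROPORTION
        and r.identity >= MIN_IDENTITY
    ]


def map_read_to_genes(read: LongRead, ann: GenomeAnnotation) -> set[str]:
    """Genes with >= 3 annotated junctions exactly matched by the read."""
    hits: set[str] = set()
    read_junctions = set(read.junctions)
    for g in ann.genes.values():
        if g.chrom != read.chrom:
            continue
        if len(read_junctions & g.junctions()) >= MIN_JUNCTIONS_PER_GENE:
            hits.add(g.id)
    return hits


def detect_cg_long(reads, ann: GenomeAnnotation) -> list[CGCandidate]:
    """CG candidates from reads mapping across exactly two co-oriented genes."""
    out: list[CGCandidate] = []
    for read in reads:
        genes = sorted(map_read_to_genes(read, ann))
        if len(genes) != 2:
            continue
        a, b = (ann.genes[g] for g in genes)
        if a.strand != b.strand:
            continue
        if ann.is_encapsulated(a, b) or ann.is_encapsulated(b, a):
            continue
        up, dn = (a, b) if a.start <= b.start else (b, a)
        if up.strand == "-":
            up, dn = dn, up
        # the inter-gene junction bridges the two gene spans
        bridge = None
        for lo, hi in read.junctions:
            g_lo = next((g for g in (a, b) if g.start <= lo <= g.end), None)
            g_hi = next((g for g in (a, b) if g.start <= hi <= g.end), None)
            if g_lo is not None and g_hi is not None and g_lo.id != g_hi.id:
                bridge = (lo, hi)
                break
        if bridge is None:
            continue
        donor, acceptor = intron_to_donor_acceptor(*bridge, up.strand)
        out.append(
            CGCandidate(
                upstream_gene=up.id,
                downstream_gene=dn.id,
                chrom=read.chrom,
                strand=up.strand,
                donor=donor,
                acceptor=acceptor,
                read_id=read.id,
            )
        )
    out.sort(key=lambda c: (c.chrom, c.donor, c.acceptor, c.read_id))
    return out


def validate_cg(cg, reads, tolerance_bp: int = 0) -> int:
    """Count reads carrying a junction equal to the CG's donor/acceptor.

    Matching is exact by default; ``tolerance_bp`` widens it to a +/- window
    on both coordinates.
    """
    lo, hi = (
        (cg.donor, cg.acceptor) if cg.strand == "+" else (cg.acceptor, cg.donor)
    )
    n = 0
    for read in reads:
        if read.chrom != cg.chrom:
            continue
        for a, b in read.junctions:
            if abs(a - lo) <= tolerance_bp and abs(b - hi) <= tolerance_bp:
                n += 1
                break
    return n


# ---------------------------------------------------------------------------
# TSV interchange (BED12-like junction-chain encoding)
# ---------------------------------------------------------------------------

def write_longread_table(reads, path) -> None:
    rows = []
    for r in reads:
        chain = ";".join(f"{a}-{b}" for a, b in r.junctions)
        rows.append(
            {
                "read_id": r.id,
                "chrom": r.chrom,
                "strand": r.strand,
                "junctions": chain,
                "aligned_proportion": r.aligned_proportion,
                "identity": r.identity,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_longread_table(path) -> list[LongRead]:
    df = pd.read_csv(path, sep="\t", dtype={"junctions": str})
    reads = []
    for row in df.itertuples(index=False):
        chain = []
        if isinstance(row.junctions, str) and row.junctions:
            for part in row.junctions.split(";"):
                a, b = part.split("-")
                chain.append((int(a), int(b)))
        reads.append(
            LongRead(
                id=row.read_id,
                chrom=row.chrom,
                strand=row.strand,
                junctions=chain,
                aligned_proportion=float(row.aligned_proportion),
                identity=float(row.identity),
            )
        )
    return reads
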