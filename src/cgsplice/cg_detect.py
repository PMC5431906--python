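"""Conjoined-gene (CG) detection from splice-junction evidence.

A CG call is a splice junction whose donor lies in one gene and whose
acceptor lies in a distinct downstream gene, with both genes co-oriented on
the same chromosome and neither encapsulated within the other.  Calls are
filtered on gene expression (>= 50 reads for both partners), a rule-based
splice score (both boundaries annotated and canonical GT..AG intronic ends,
worth one point each), exon-boundary agreement, and a deterministic
confidence that stands in for a learned fusion-caller probability:
``confidence = (splice_score / 4) * min(1, split_reads / 5)``, i.e. 1.0 for a
canonical boundary junction with at least five split reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import (
    AnnotationError,
    Gene,
    GenomeAnnotation,
    donor_acceptor_to_intron,
)

__all__ = [
    "CGEvent",
    "CGFilterConfig",
    "detect_cg",
    "splice_score",
    "classify_splicing_pattern",
    "interrupted_index",
    "splicing_index",
    "collapse_cg_partners",
    "cg_overlap_sets",
    "gene_expression_reads",
    "cg_table",
]

JUNCTION_COLUMNS = ["chrom", "strand", "donor", "acceptor", "sample", "count"]
COVERAGE_COLUMNS = ["feature_id", "region", "sample", "mean_depth"]


@dataclass
class CGEvent:
    upstream_gene: str
    downstream_gene: str
    chrom: str
    strand: str
    donor: int
    acceptor: int
    split_reads: int
    spanning_pairs: int = 0
    splice_score: int = 0
    boundary_ok: bool = False
    confidence: float = 0.0
    up_skipped: int = 0
    dn_skipped: int = 0
    interrupted_index_up: float = math.nan
    interrupted_index_dn: float = math.nan
    splicing_index_up: float = math.nan
    splicing_index_dn: float = math.nan

    @property
    def pair(self) -> tuple[str, str]:
        return (self.upstream_gene, self.downstream_gene)


@dataclass
class CGFilterConfig:
    min_gene_expression_reads: int = 50
    require_splice_score: int = 4
    require_exon_boundaries: bool = True
    min_confidence: float = 0.9
    same_strand: bool = True
    min_split_reads: int = 1


def gene_expression_reads(
    junctions: pd.DataFrame, ann: GenomeAnnotation
) -> dict[str, int]:
    """Total junction reads assigned to each gene, pooled over samples.

    A junction row is assigned to a gene when both its coordinates fall
    within the gene span on the matching strand; inter-gene (candidate CG)
    junctions contribute to neither partner.
    """
    totals = {gid: 0 for gid in ann.genes}
    for row in junctions.itertuples(index=False):
        lo, hi = donor_acceptor_to_intron(row.donor, row.acceptor, row.strand)
        for g in ann.genes_containing(row.chrom, lo, row.strand):
            if g.start <= lo and hi <= g.end:
                totals[g.id] += int(row.count)
    return totals


def splice_score(
    chrom: str,
    strand: str,
    donor: int,
    acceptor: int,
    ann: GenomeAnnotation,
    genome: dict[str, str],
    up_gene: Gene | None = None,
    dn_gene: Gene | None = None,
) -> tuple[int, bool]:
    """Rule-based 0-4 splice score and boundary flag for a junction.

    One point each for: donor at an annotated exon 3' boundary; acceptor at
    an annotated exon 5' boundary; intervening sequence starting with GT; and
    ending with AG (strand-aware).  Returns ``(score, boundary_ok)`` where
    the flag requires both boundary points.
    """
    lo, hi = donor_acceptor_to_intron(donor, acceptor, strand)
    donor_ok = acceptor_ok = False
    up_candidates = [up_gene] if up_gene else ann.genes_containing(chrom, donor, strand)
    dn_candidates = [dn_gene] if dn_gene else ann.genes_containing(chrom, acceptor, strand)
    for g in up_candidates:
        donors, _ = g.exon_boundaries()
        if donor in donors:
            donor_ok = True
            break
    for g in dn_candidates:
        _, acceptors = g.exon_boundaries()
        if acceptor in acceptors:
            acceptor_ok = True
            break
    seq = genome[chrom][lo:hi].upper()
    if strand == "-":
        seq = _revcomp(seq)
    score = int(donor_ok) + int(acceptor_ok)
    if len(seq) >= 4:
        score += int(seq[:2] == "GT") + int(seq[-2:] == "AG")
    return score, donor_ok and acceptor_ok


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def detect_cg(
    junctions: pd.DataFrame,
    ann: GenomeAnnotation,
    genome: dict[str, str],
    coverage: pd.DataFrame | None = None,
    cfg: CGFilterConfig | None = None,
) -> list[CGEvent]:
    """Call CG events from a junction count table.

    Junction counts are pooled across samples per (chrom, strand, donor,
    acceptor).  Output order is deterministic: (chrom, donor, acceptor,
    downstream gene id).  Row order of the input table does not affect the
    result.
    """
    cfg = cfg or CGFilterConfig()
    known = set()
    for g in ann.genes.values():
        known.add(g.chrom)
    bad = set(junctions["chrom"]) - known
    if bad:
        raise AnnotationError(f"junction table references unknown chromosomes: {sorted(bad)}")

    pooled = (
        junctions.groupby(["chrom", "strand", "donor", "acceptor"], as_index=False)[
            "count"
        ].sum()
    )
    expression = gene_expression_reads(junctions, ann)

    events: list[CGEvent] = []
    for row in pooled.itertuples(index=False):
        count = int(row.count)
        if count < cfg.min_split_reads:
            continue
        strand = row.strand
        donor_genes = [
            g
            for g in ann.genes_containing(row.chrom, row.donor, strand)
            if cfg.same_strand is False or g.strand == strand
        ]
        acceptor_genes = [
            g
            for g in ann.genes_containing(row.chrom, row.acceptor, strand)
            if cfg.same_strand is False or g.strand == strand
        ]
        for up in donor_genes:
            for dn in acceptor_genes:
                if up.id == dn.id:
                    continue
                if ann.is_encapsulated(up, dn) or ann.is_encapsulated(dn, up):
                    continue
                # transcription must run from the upstream to the downstream gene
                if strand == "+":
                    if not (up.start < dn.start and row.donor < row.acceptor):
                        continue
                else:
                    if not (up.start > dn.start and row.donor > row.acceptor):
                        continue
                if expression.get(up.id, 0) < cfg.min_gene_expression_reads:
                    continue
                if expression.get(dn.id, 0) < cfg.min_gene_expression_reads:
                    continue
                score, boundary_ok = splice_score(
                    row.chrom, strand, row.donor, row.acceptor, ann, genome, up, dn
                )
                if score < cfg.require_splice_score:
                    continue
                if cfg.require_exon_boundaries and not boundary_ok:
                    continue
                confidence = (score / 4.0) * min(1.0, count / 5.0)
                if confidence < cfg.min_confidence:
                    continue
                ev = CGEvent(
                    upstream_gene=up.id,
                    downstream_gene=dn.id,
                    chrom=row.chrom,
                    strand=strand,
                    donor=int(row.donor),
                    acceptor=int(row.acceptor),
                    split_reads=count,
                    splice_score=score,
                    boundary_ok=boundary_ok,
                    confidence=confidence,
                )
                try:
                    ev.up_skipped, ev.dn_skipped = classify_splicing_pattern(ev, ann)
                except AnnotationError:
                    pass
                if coverage is not None:
                    for side in ("up", "dn"):
                        try:
                            idx = interrupted_index(coverage, ev, side)
                        except (AnnotationError, KeyError):
                            idx = math.nan
                        setattr(ev, f"interrupted_index_{side}", idx)
                events.append(ev)
    events.sort(key=lambda e: (e.chrom, e.donor, e.acceptor, e.downstream_gene))
    return events


def classify_splicing_pattern(cg: CGEvent, ann: GenomeAnnotation) -> tuple[int, int]:
    """Exon-skip counts of a CG against each partner's reference transcript.

    ``up_skipped`` counts upstream-gene exons strictly 3' of the donor exon,
    ``dn_skipped`` downstream-gene exons strictly 5' of the acceptor exon;
    the modal read-through pattern (donor at the second-to-last exon,
    acceptor at the second exon) is therefore encoded (1, 1).
    """
    up = ann.genes[cg.upstream_gene]
    dn = ann.genes[cg.downstream_gene]
    up_tx = up.longest_transcript()
    dn_tx = dn.longest_transcript()
    donor_idx = acceptor_idx = None
    for i, e in enumerate(up_tx.exons):
        if (e.end if up.strand == "+" else e.start) == cg.donor:
            donor_idx = i
            break
    for i, e in enumerate(dn_tx.exons):
        if (e.start if dn.strand == "+" else e.end) == cg.acceptor:
            acceptor_idx = i
            break
    if donor_idx is None or acceptor_idx is None:
        raise AnnotationError(
            f"CG {cg.pair}: junction not at annotated exon boundaries"
        )
    return len(up_tx.exons) - 1 - donor_idx, acceptor_idx


def interrupted_index(
    coverage: pd.DataFrame, cg: CGEvent, participant: str
) -> float:
    """Coverage ratio of the CG-retained over the CG-removed gene portion.

    Zero coverage over the removed portion yields ``inf`` (flagged by the
    caller via ``math.isinf``); an absent retained portion is an error.
    """
    gene = cg.upstream_gene if participant == "up" else cg.downstream_gene
    sub = coverage[coverage["feature_id"] == gene]
    retained = sub[sub["region"] == "retained"]["mean_depth"]
    removed = sub[sub["region"] == "removed"]["mean_depth"]
    if retained.empty:
        raise AnnotationError(f"no retained-portion coverage for {gene}")
    r = float(retained.mean())
    x = float(removed.mean()) if not removed.empty else 0.0
    if x == 0.0:
        return math.inf
    return r / x


def splicing_index(wildtype_pairs: int, cg_support_reads: int) -> float:
    """Wild-type junction-spanning pairs per CG-supporting junction read."""
    if cg_support_reads < 1:
        raise ValueError("a CG must have >= 1 supporting read")
    return wildtype_pairs / cg_support_reads


def collapse_cg_partners(events) -> pd.DataFrame:
    """Collapse CG calls to unique ordered partner pairs.

    Donor/acceptor variation between calls on the same ordered gene pair is
    treated as isoform variation of one CG; the isoform count is recorded.
    """
    counts: dict[tuple[str, str], int] = {}
    for ev in events:
        counts[ev.pair] = counts.get(ev.pair, 0) + 1
    rows = [
        {"upstream_gene": u, "downstream_gene": d, "isoforms": n}
        for (u, d), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["upstream_gene", "downstream_gene", "isoforms"])


def cg_overlap_sets(pair_sets: dict[str, set]) -> dict:
    """Shared/exclusive partition of CG partner-pair sets across datasets."""
    if len(pair_sets) < 2:
        raise ValueError("need >= 2 datasets")
    names = sorted(pair_sets)
    all_shared = set.intersection(*(pair_sets[n] for n in names))
    exclusive = {
        n: pair_sets[n] - set.union(*(pair_sets[m] for m in names if m != n))
        for n in names
    }
    pairwise = {
        (a, b): pair_sets[a] & pair_sets[b]
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return {"shared": all_shared, "exclusive": exclusive, "pairwise": pairwise}


def cg_table(events) -> pd.DataFrame:
    cols = [
        "upstream_gene", "downstream_gene", "chrom", "strand", "donor",
        "acceptor", "split_reads", "spanning_pairs", "splice_score",
        "boundary_ok", "confidence", "up_skipped", "dn_skipped",
        "interrupted_index_up", "interrupted_index_dn",
        "splicing_index_up", "splicing_index_dn",
    ]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events], columns=cols)
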