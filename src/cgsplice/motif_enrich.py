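"""RNA-binding-protein motif density enrichment and 3'-end signal scanning.

A PWM match is a window whose log2 odds score (position probabilities over
background base frequencies) reaches at least 80% of the PWM's maximum
achievable score under the same background; scanning is sense-strand only,
with T and U equivalent.  The motif density of a region is d = m / l, the
number of passing windows per base pair of region.  Densities of a group of
events are compared against a background group per (region, motif) cell by a
Welch t-test on the pooled ranks, Benjamini-Hochberg adjusted across all
cells of the comparison, with the Kerby simple-difference rank-biserial
correlation as the effect size (favorable minus unfavorable pair
proportion).

The module also extracts the seven skipped-exon regions (upstream exon,
intron halves capped at 600 bp per intron, the SE itself, downstream intron
halves, downstream exon) and the four conjoined-gene regions (penultimate
and last exons of the upstream partner, first and second exons of the
downstream partner), and scans 3'-end signals: the canonical A(A/U)UAAA
poly(A) signal within 50 bp upstream of a poly(A) site, CFIm-bound UGUA
within 150 bp upstream, and a U/GU-rich downstream element (DSE) within 50
bp downstream.  A DSE is a run of >= 6 nt of uracils interspersed with at
most three non-adjacent guanines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, rankdata, ttest_ind
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationError, Gene, GenomeAnnotation

__all__ = [
    "PWM",
    "MotifDensity",
    "EnrichmentCell",
    "read_pwm_file",
    "write_pwm_file",
    "scan_pwm",
    "motif_density",
    "density_enrichment",
    "MotifEnrichment",
    "dedup_motif_families",
    "cluster_motif_patterns",
    "extract_se_regions",
    "extract_cg_regions",
    "find_polya_signals",
    "is_dse",
    "background_frequencies",
    "SE_REGIONS",
    "CG_REGIONS",
]

SE_REGIONS = ("up", "up5in", "up3in", "SE", "dn5in", "dn3in", "dn")
CG_REGIONS = ("minus1_exon", "last_exon", "first_exon", "plus1_exon")

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE["U"] = _CODE["T"]


@dataclass
class PWM:
    id: str
    rbp_name: str
    family: str
    matrix: np.ndarray  # positions x 4 (A, C, G, U) probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.id}: matrix must be positions x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id}: rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_consensus(
        cls, consensus: str, id: str = "consensus", rbp_name: str = "",
        family: str = "", pseudo: float = 1e-3,
    ) -> "PWM":
        """Near-deterministic PWM for a consensus sequence."""
        m = np.full((len(consensus), 4), pseudo)
        for i, base in enumerate(consensus.upper()):
            m[i, _CODE[base]] = 1.0 - 3 * pseudo
        return cls(id=id, rbp_name=rbp_name or id, family=family or id, matrix=m)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class MotifDensity:
    region_id: str
    motif_id: str
    m: int
    l: int

    @property
    def d(self) -> float:
        return motif_density(self.m, self.l)


@dataclass
class EnrichmentCell:
    region: str
    motif_id: str
    p: float
    p_adj: float
    effect: float
    significant: bool


# ---------------------------------------------------------------------------
# PWM text format: ">id<TAB>rbp_name<TAB>family" then one line per position
# with four whitespace-separated probabilities (A C G U).
# ---------------------------------------------------------------------------

def write_pwm_file(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id}\t{p.rbp_name}\t{p.family}\n")
            for row in p.matrix:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_pwm_file(path) -> list[PWM]:
    pwms: list[PWM] = []
    header: tuple[str, str, str] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is not None:
            m = np.asarray(rows, dtype=float)
            m = m / m.sum(axis=1, keepdims=True)  # re-normalize rounded rows
            pwms.append(PWM(id=header[0], rbp_name=header[1], family=header[2], matrix=m))
        header, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                parts = (line[1:].split("\t") + ["", ""])[:3]
                header = (parts[0], parts[1], parts[2])
            else:
                rows.append([float(v) for v in line.split()])
    flush()
    return pwms


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _CODE.get(ch, -1)
    return out


def background_frequencies(sequences: Sequence[str]) -> np.ndarray:
    """Pooled A/C/G/U frequencies of a sequence set (scanner background)."""
    counts = np.zeros(4)
    for s in sequences:
        codes = _encode(s)
        for c in codes[codes >= 0]:
            counts[c] += 1
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold_frac: float = 0.8,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Start positions of windows scoring >= threshold_frac * max score.

    The per-window score is sum_i log2(p_i(base) / bg(base)); the maximum
    achievable score uses the best base at every position under the same
    background.  Windows containing non-ACGU characters never match.
    """
    bg = np.asarray(background, dtype=float) if background is not None else pwm.background
    L = len(pwm)
    codes = _encode(sequence)
    n = codes.size - L + 1
    if n <= 0:
        return np.array([], dtype=int)
    lut = np.log2(np.maximum(pwm.matrix, 1e-300) / bg)  # positions x 4
    max_score = float(lut.max(axis=1).sum())
    threshold = threshold_frac * max_score
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = lut[np.arange(L)[None, :], safe].sum(axis=1)
    hits = np.flatnonzero(valid & (scores >= threshold - 1e-12))
    return hits


def motif_density(m: int, l: int) -> float:
    """Motif density d = m / l (matches per bp of region)."""
    if l <= 0:
        raise ValueError("region length must be positive")
    return m / l


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def _rank_welch(group: np.ndarray, other: np.ndarray) -> float:
    import warnings

    pooled = np.concatenate([group, other])
    ranks = rankdata(pooled)
    rg, ro = ranks[: group.size], ranks[group.size :]
    if np.all(pooled == pooled[0]):
        return 1.0
    with warnings.catch_warnings():
        # near-constant ranks trip scipy's catastrophic-cancellation warning;
        # the resulting nan is mapped to the null p below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = ttest_ind(rg, ro, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _rank_biserial(group: np.ndarray, other: np.ndarray) -> float:
    """Kerby simple difference: favorable minus unfavorable pair proportion."""
    u = mannwhitneyu(group, other, alternative="two-sided").statistic
    return float(2.0 * u / (group.size * other.size) - 1.0)


def density_enrichment(
    group: pd.DataFrame,
    other: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(region, motif) density comparison of a group against the rest.

    Both inputs are long tables with columns ``region``, ``motif_id`` and
    ``density`` (one row per event).  Each cell is tested by a two-sided
    Welch t-test on pooled ranks; BH adjustment spans every cell of the
    comparison, and the rank-biserial effect is positive when the group's
    densities are higher.
    """
    cells = []
    keys = sorted(
        set(map(tuple, group[["region", "motif_id"]].itertuples(index=False)))
        & set(map(tuple, other[["region", "motif_id"]].itertuples(index=False)))
    )
    g_idx = group.groupby(["region", "motif_id"])["density"]
    o_idx = other.groupby(["region", "motif_id"])["density"]
    for region, motif in keys:
        gv = g_idx.get_group((region, motif)).to_numpy(float)
        ov = o_idx.get_group((region, motif)).to_numpy(float)
        if gv.size < 3 or ov.size < 3:
            raise ValueError(f"cell ({region}, {motif}): need n >= 3 per side")
        if np.all(gv == gv[0]) and np.all(ov == gv[0]):
            p, effect = 1.0, 0.0  # identical constants on both sides
        else:
            p = _rank_welch(gv, ov)
            effect = _rank_biserial(gv, ov)
        cells.append({"region": region, "motif_id": motif, "p": p, "effect": effect})
    out = pd.DataFrame(cells)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out[["region", "motif_id", "p", "p_adj", "effect", "significant"]]


class MotifEnrichment:
    """Model object: PWM scan + rank enrichment of a group vs background.

    Parameters
    ----------
    group_regions, background_regions : mapping event -> {region: sequence}
    pwms : the motif library to scan.
    """

    def __init__(self, group_regions: dict, background_regions: dict, pwms: Sequence[PWM]):
        self.group_regions = group_regions
        self.background_regions = background_regions
        self.pwms = list(pwms)

    def densities(self, regions_by_event: dict, background: np.ndarray) -> pd.DataFrame:
        rows = []
        for event, regions in regions_by_event.items():
            for region, seq in regions.items():
                for pwm in self.pwms:
                    hits = scan_pwm(seq, pwm, background=background)
                    rows.append(
                        {
                            "event": event,
                            "region": region,
                            "motif_id": pwm.id,
                            "m": int(hits.size),
                            "l": len(seq),
                            "density": motif_density(hits.size, len(seq)) if len(seq) else 0.0,
                        }
                    )
        return pd.DataFrame(rows)

    def fit(self, alpha: float = 0.05) -> "MotifEnrichmentResult":
        all_seqs = [
            s
            for regions in (*self.group_regions.values(), *self.background_regions.values())
            for s in regions.values()
        ]
        bg = background_frequencies(all_seqs)
        gd = self.densities(self.group_regions, bg)
        od = self.densities(self.background_regions, bg)
        table = density_enrichment(gd, od, alpha=alpha)
        return MotifEnrichmentResult(table=table, group_densities=gd, background_densities=od, base_frequencies=bg)


@dataclass
class MotifEnrichmentResult:
    table: pd.DataFrame
    group_densities: pd.DataFrame
    background_densities: pd.DataFrame
    base_frequencies: np.ndarray

    def summary(self) -> str:
        sig = self.table[self.table["significant"]]
        lines = [
            "Motif density enrichment",
            f"  cells tested: {len(self.table)}  significant (BH < 0.05): {len(sig)}",
        ]
        for row in sig.itertuples(index=False):
            direction = "enriched" if row.effect > 0 else "depleted"
            lines.append(
                f"  {row.motif_id} in {row.region}: {direction}, "
                f"effect {row.effect:+.2f}, adj p {row.p_adj:.3g}"
            )
        return "\n".join(lines)


def dedup_motif_families(
    cells: pd.DataFrame,
    family_map: dict[str, str],
    representative_map: dict[str, str] | None = None,
) -> list[str]:
    """One motif per RBP family from an enrichment cell table.

    A family's representative member's motif wins outright when present;
    otherwise the motif significant in the most regions is kept, ties broken
    by lexicographically smallest motif id.
    """
    missing = set(cells["motif_id"]) - set(family_map)
    if missing:
        raise ValueError(f"family map does not cover motifs: {sorted(missing)}")
    representative_map = representative_map or {}
    sig_regions = (
        cells[cells["significant"]].groupby("motif_id")["region"].nunique().to_dict()
    )
    chosen: list[str] = []
    by_family: dict[str, list[str]] = {}
    for motif in sorted(set(cells["motif_id"])):
        by_family.setdefault(family_map[motif], []).append(motif)
    for family in sorted(by_family):
        motifs = by_family[family]
        rep = representative_map.get(family)
        if rep is not None and rep in motifs:
            chosen.append(rep)
            continue
        chosen.append(
            min(motifs, key=lambda m: (-sig_regions.get(m, 0), m))
        )
    return chosen


def cluster_motif_patterns(effects: pd.DataFrame) -> pd.Series:
    """Group motifs by their signed effect pattern across regions.

    Average-linkage hierarchical clustering on Euclidean distances between
    effect rows; flat clusters are formed at a co-phenetic distance of half
    the maximum co-phenetic distance between any two motifs.
    """
    if len(effects) < 1:
        raise ValueError("no motifs to cluster")
    if len(effects) == 1:
        return pd.Series([1], index=effects.index)
    x = effects.to_numpy(dtype=float)
    d = pdist(x, metric="euclidean")
    if np.all(d == 0):
        return pd.Series(1, index=effects.index)
    link = average(d)
    coph = cophenet(link)
    threshold = 0.5 * float(coph.max())
    labels = fcluster(link, t=threshold, criterion="distance")
    return pd.Series(labels, index=effects.index)


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _oriented(genome: dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    seq = genome[chrom][start:end]
    return seq if strand == "+" else _revcomp(seq)


def _intron_halves(length: int, cap: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(left, right) genomic sub-intervals of an intron [0, length).

    Introns no longer than the cap are split at the midpoint; longer introns
    contribute cap/2 bp adjacent to each splice site.
    """
    if length <= cap:
        mid = length // 2
        return (0, mid), (mid, length)
    half = cap // 2
    return (0, half), (length - half, length)


def extract_se_regions(
    se_event,
    genome: dict[str, str],
    intron_cap: int = 600,
) -> dict[str, str]:
    """Seven named sequences around a skipped exon, transcript-oriented.

    ``se_event`` carries chrom, strand and the genomic intervals of the
    upstream constitutive exon, the SE, and the downstream constitutive exon
    (attributes ``upstream_exon``, ``se``, ``downstream_exon``).  Intron
    halves are named for their adjacency: ``up5in`` abuts the upstream
    exon's 5' splice site, ``up3in`` the SE's 3' splice site, and
    analogously downstream.
    """
    chrom, strand = se_event.chrom, se_event.strand
    exons = [tuple(se_event.upstream_exon), tuple(se_event.se), tuple(se_event.downstream_exon)]
    exons_tx = sorted(exons, key=lambda e: e[0], reverse=(strand == "-"))
    (up_s, up_e), (se_s, se_e), (dn_s, dn_e) = exons_tx
    regions: dict[str, tuple[int, int]] = {}
    regions["up"] = (up_s, up_e)
    regions["SE"] = (se_s, se_e)
    regions["dn"] = (dn_s, dn_e)

    def halves(lo: int, hi: int) -> tuple[tuple[int, int], tuple[int, int]]:
        (l0, l1), (r0, r1) = _intron_halves(hi - lo, intron_cap)
        return (lo + l0, lo + l1), (lo + r0, lo + r1)

    if strand == "+":
        if not (up_e <= se_s and se_e <= dn_s):
            raise AnnotationError("SE event exons are not ordered/disjoint")
        left, right = halves(up_e, se_s)
        regions["up5in"], regions["up3in"] = left, right
        left, right = halves(se_e, dn_s)
        regions["dn5in"], regions["dn3in"] = left, right
    else:
        if not (dn_e <= se_s and se_e <= up_s):
            raise AnnotationError("SE event exons are not ordered/disjoint")
        left, right = halves(se_e, up_s)
        # transcript 5' side of the upstream intron is the genomic right half
        regions["up5in"], regions["up3in"] = right, left
        left, right = halves(dn_e, se_s)
        regions["dn5in"], regions["dn3in"] = right, left
    return {
        name: _oriented(genome, chrom, s, e, strand)
        for name, (s, e) in ((n, regions[n]) for n in SE_REGIONS)
    }


def extract_cg_regions(cg, ann: GenomeAnnotation, genome: dict[str, str]) -> dict[str, str]:
    """Penultimate/last exon of the upstream partner and first/second exon of
    the downstream partner, in transcript orientation."""
    up = ann.genes[cg.upstream_gene]
    dn = ann.genes[cg.downstream_gene]
    up_ex = up.longest_transcript().exons
    dn_ex = dn.longest_transcript().exons
    if len(up_ex) < 2 or len(dn_ex) < 2:
        raise AnnotationError("CG motif regions require >= 2 exons per partner")
    picks = {
        "minus1_exon": up_ex[-2],
        "last_exon": up_ex[-1],
        "first_exon": dn_ex[0],
        "plus1_exon": dn_ex[1],
    }
    return {
        name: _oriented(genome, e.chrom, e.start, e.end, e.strand)
        for name, e in picks.items()
    }


def sample_background_genes(
    ann: GenomeAnnotation,
    exclude: set[str],
    n: int = 5000,
    min_exons: int = 4,
    seed: int | None = None,
) -> list[str]:
    """Random non-CG genes with >= ``min_exons`` exons (background set)."""
    rng = np.random.default_rng(seed)
    pool = sorted(
        gid
        for gid, g in ann.genes.items()
        if gid not in exclude and len(g.longest_transcript().exons) >= min_exons
    )
    if len(pool) <= n:
        return pool
    return sorted(rng.choice(pool, size=n, replace=False))


# ---------------------------------------------------------------------------
# 3'-end signals
# ---------------------------------------------------------------------------

def is_dse(sequence: str) -> bool:
    """U/GU-rich downstream element: some window of >= 6 nt made of uracils
    with at most three interspersed, non-adjacent guanines."""
    s = sequence.upper().replace("T", "U")
    n = len(s)
    for i in range(n - 5):
        window = s[i : i + 6]
        if any(ch not in "UG" for ch in window):
            continue
        if "GG" in window:
            continue
        if window.count("G") <= 3:
            return True
    return False


@dataclass
class PolyASignalReport:
    gene_id: str
    site: int
    canonical_signal: bool
    canonical_count: int
    ugua_count: int
    dse: bool
    n_sites_gene: int


def find_polya_signals(
    gene: Gene,
    site: int,
    genome: dict[str, str],
    ann: GenomeAnnotation | None = None,
    signal_window: int = 50,
    ugua_window: int = 150,
    dse_window: int = 50,
) -> PolyASignalReport:
    """Scan 3'-end signals around a poly(A) site, strand-aware.

    Canonical A(A/U)UAAA hexamers are counted within ``signal_window`` bp
    upstream (transcript orientation) of the site, UGUA within
    ``ugua_window`` bp upstream, and the DSE rule is applied to
    ``dse_window`` bp downstream.
    """
    chrom_seq = genome[gene.chrom]
    if not (0 <= site <= len(chrom_seq)):
        raise AnnotationError(f"poly(A) site {site} outside sequence bounds")
    if gene.strand == "+":
        up_sig = chrom_seq[max(0, site - signal_window) : site]
        up_ugua = chrom_seq[max(0, site - ugua_window) : site]
        down = chrom_seq[site : site + dse_window]
    else:
        up_sig = _revcomp(chrom_seq[site : site + signal_window])
        up_ugua = _revcomp(chrom_seq[site : site + ugua_window])
        down = _revcomp(chrom_seq[max(0, site - dse_window) : site])
    up_sig = up_sig.upper().replace("T", "U")
    up_ugua = up_ugua.upper().replace("T", "U")
    canonical = sum(
        1
        for i in range(len(up_sig) - 5)
        if up_sig[i] == "A" and up_sig[i + 1] in "AU" and up_sig[i + 2 : i + 6] == "UAAA"
    )
    ugua = sum(1 for i in range(len(up_ugua) - 3) if up_ugua[i : i + 4] == "UGUA")
    n_sites = len(ann.polya_sites.get(gene.id, [])) if ann is not None else 0
    return PolyASignalReport(
        gene_id=gene.id,
        site=site,
        canonical_signal=canonical > 0,
        canonical_count=canonical,
        ugua_count=ugua,
        dse=is_dse(down),
        n_sites_gene=n_sites,
    )
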