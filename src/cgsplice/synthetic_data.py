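"""Synthetic study generator: annotations, sequence, dose-responsive evidence.

The generator emulates the evidence a CLK-inhibitor dose-response RNA-Seq
study produces, with known ground truth: tandem same-strand gene pairs with
configurable intergenic distances on a synthetic chromosome; per-dose
binomially sampled inclusion/exclusion junction counts following monotone or
flat PSI dose curves; dose-increasing conjoined-gene (CG) read-through
junctions that *steal* reads from the upstream partner's terminal junction
(read-through forms at the expense of the canonical isoform, so total
terminal-junction depth is conserved); planted motif occurrences at
specified densities; long reads as junction chains with optional coordinate
jitter and alignment-quality attributes; and control/treatment siRNA CG
count tables with planted effects.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import (
    Exon,
    Gene,
    GenomeAnnotation,
    Transcript,
    write_annotation,
    write_fasta,
)
from .longread_validate import LongRead

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "GroundTruth",
    "PlantedCG",
    "MotifPlantSpec",
    "simulate_annotation",
    "simulate_dose_response_profiles",
    "simulate_junction_counts",
    "simulate_cg_readthrough",
    "plant_motifs",
    "simulate_long_reads",
    "simulate_sirna_counts",
    "simulate_study",
]

DEFAULT_DOSE_GRID = (0.0, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0)  # inhibitor conc., uM
# read-through probability per dose: steep rise past the inhibitor's cellular
# IC50 (between the 0.1 and 0.5 uM doses), saturating at high concentration
DEFAULT_CG_RATE_CURVE = (0.0, 0.02, 0.05, 0.2, 0.35, 0.5, 0.6)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is infeasible or inconsistent."""


@dataclass
class SimulationConfig:
    n_gene_pairs: int = 20
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (80, 200)
    intron_len: tuple[int, int] = (80, 300)
    intergenic_len: tuple[int, int] = (500, 5000)
    pair_spacing: tuple[int, int] = (8000, 15000)
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    depth: float = 50.0
    cg_rate_curve: tuple[float, ...] = DEFAULT_CG_RATE_CURVE
    psi_shape_proportions: dict[str, float] = field(
        default_factory=lambda: {"up": 1 / 3, "down": 1 / 3, "flat": 1 / 3}
    )
    psi_effect_size: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len", "pair_spacing"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} range must be positive and ordered")
        if self.n_gene_pairs < 1:
            raise ConfigurationError("need >= 1 gene pair")
        if any(b <= a for a, b in zip(self.dose_grid, self.dose_grid[1:])):
            raise ConfigurationError("dose_grid must be strictly increasing")
        if len(self.cg_rate_curve) != len(self.dose_grid):
            raise ConfigurationError("cg_rate_curve must match the dose grid")
        if any(not 0 <= r <= 1 for r in self.cg_rate_curve):
            raise ConfigurationError("read-through rates must lie in [0, 1]")
        if not np.isclose(sum(self.psi_shape_proportions.values()), 1.0):
            raise ConfigurationError("psi shape proportions must sum to 1")
        if self.depth < 0 or self.noise_sd < 0:
            raise ConfigurationError("depth and noise_sd must be non-negative")
        if not 0 <= self.psi_effect_size <= 1:
            raise ConfigurationError("psi_effect_size must lie in [0, 1]")

    @property
    def dose_labels(self) -> list[str]:
        return [f"dose_{d:g}" for d in self.dose_grid]


@dataclass(frozen=True)
class PlantedCG:
    upstream_gene: str
    downstream_gene: str
    chrom: str
    strand: str
    donor: int
    acceptor: int


@dataclass(frozen=True)
class MotifPlantSpec:
    intervals: tuple[tuple[str, int, int], ...]
    consensus: str
    density: float


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    dose_labels: list[str]
    psi_matrix: pd.DataFrame | None = None          # observed (noisy) PSI
    noiseless_psi: pd.DataFrame | None = None
    cluster_labels: pd.Series | None = None         # event -> up/down/flat
    planted_cgs: list[PlantedCG] = field(default_factory=list)
    planted_motifs: list[MotifPlantSpec] = field(default_factory=list)
    sirna_effects: dict[str, list[str]] = field(default_factory=dict)

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        if self.psi_matrix is not None:
            self.psi_matrix.to_csv(os.path.join(outdir, "true_psi.tsv"), sep="\t")
        if self.cluster_labels is not None:
            self.cluster_labels.rename("label").to_frame().to_csv(
                os.path.join(outdir, "true_labels.tsv"), sep="\t"
            )
        cg_cols = [f.name for f in dataclasses.fields(PlantedCG)]
        pd.DataFrame(
            [dataclasses.asdict(c) for c in self.planted_cgs], columns=cg_cols
        ).to_csv(os.path.join(outdir, "planted_cgs.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "sirna_effects.json"), "w") as fh:
            json.dump(self.sirna_effects, fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, outdir: str | os.PathLike, dose_labels: list[str]) -> "GroundTruth":
        outdir = str(outdir)
        truth = cls(dose_labels=dose_labels)
        psi_path = os.path.join(outdir, "true_psi.tsv")
        if os.path.exists(psi_path):
            truth.psi_matrix = pd.read_csv(psi_path, sep="\t", index_col=0)
        lab_path = os.path.join(outdir, "true_labels.tsv")
        if os.path.exists(lab_path):
            truth.cluster_labels = pd.read_csv(lab_path, sep="\t", index_col=0)["label"]
        cg_path = os.path.join(outdir, "planted_cgs.tsv")
        if os.path.exists(cg_path):
            df = pd.read_csv(cg_path, sep="\t")
            truth.planted_cgs = [PlantedCG(**row) for row in df.to_dict("records")]
        eff_path = os.path.join(outdir, "sirna_effects.json")
        if os.path.exists(eff_path):
            with open(eff_path) as fh:
                truth.sirna_effects = json.load(fh)
        return truth


# ---------------------------------------------------------------------------
# Annotation + genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_annotation(
    config: SimulationConfig, chrom: str = "chr1"
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Generate tandem same-strand gene pairs and a matching genome sequence.

    Each gene carries one multi-exon transcript with canonical GT..AG intron
    boundaries written into the sequence (the intergenic stretch between the
    pair's partners also starts GT and ends AG, so a read-through junction
    between annotated exon boundaries is splice-canonical).  A CDS spanning
    the interior exons provides UTR/CDS region structure, a poly(A) site is
    registered at each gene's 3' end, and each gene's middle exon is labeled
    as a protein-domain interval.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = GenomeAnnotation()
    pieces: list[np.ndarray] = []
    pos = 0

    def emit_seq(n: int) -> None:
        nonlocal pos
        pieces.append(_random_seq(rng, n))
        pos += n

    def make_gene(gid: str) -> Gene:
        nonlocal pos
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        splice_fixes = []  # (offset, "GT"/"AG")
        for i in range(n_ex):
            e_len = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            exons.append(Exon(chrom, pos, pos + e_len, "+"))
            emit_seq(e_len)
            if i < n_ex - 1:
                i_len = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
                splice_fixes.append((pos, "GT"))
                splice_fixes.append((pos + i_len - 2, "AG"))
                emit_seq(i_len)
        gene = Gene(id=gid, chrom=chrom, strand="+")
        tx = Transcript(id=f"{gid}.t1", gene_id=gid, exons=exons)
        if n_ex >= 3:
            tx.cds_start = exons[1].start
            tx.cds_end = exons[-2].end
        gene.transcripts[tx.id] = tx
        ann.polya_sites[gid] = [exons[-1].end]
        mid = exons[len(exons) // 2]
        ann.domains.append((chrom, mid.start, mid.end, f"{gid}_domain"))
        _fixups.extend(splice_fixes)
        return gene

    _fixups: list[tuple[int, str]] = []
    for p in range(config.n_gene_pairs):
        a = make_gene(f"G{p:03d}A")
        ig = int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
        _fixups.append((pos, "GT"))
        _fixups.append((pos + ig - 2, "AG"))
        emit_seq(ig)
        b = make_gene(f"G{p:03d}B")
        emit_seq(int(rng.integers(config.pair_spacing[0], config.pair_spacing[1] + 1)))
        ann.genes[a.id] = a
        ann.genes[b.id] = b

    codes = np.concatenate(pieces)
    seq = _BASES[codes].tobytes().decode()
    arr = bytearray(seq, "ascii")
    for off, motif in _fixups:
        arr[off : off + 2] = motif.encode()
    genome = {chrom: arr.decode()}
    ann.validate()
    return ann, genome


# ---------------------------------------------------------------------------
# Dose-response PSI profiles and junction counts
# ---------------------------------------------------------------------------

def simulate_dose_response_profiles(
    config: SimulationConfig,
    n_events: int,
    seed: int | None = None,
) -> GroundTruth:
    """PSI dose profiles with planted monotone-up/-down/flat shapes.

    Monotone events ramp linearly (in dose rank) by ``psi_effect_size``
    from a random baseline; flat events hold a constant baseline.  Gaussian
    noise with ``noise_sd`` is added and values are clipped to [0, 1];
    baselines keep the noiseless curve at least 2 SD away from the clip
    boundaries so clipping is rare.
    """
    if len(config.dose_grid) < 4:
        raise ConfigurationError("dose grid must have >= 4 doses")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shapes = list(config.psi_shape_proportions)
    probs = np.array([config.psi_shape_proportions[s] for s in shapes])
    labels = rng.choice(shapes, size=n_events, p=probs)
    k = len(config.dose_grid)
    ramp = np.linspace(0.0, 1.0, k)
    amp = config.psi_effect_size
    margin = min(0.1, max(2 * config.noise_sd, 0.02))
    noiseless = np.empty((n_events, k))
    for i, lab in enumerate(labels):
        if lab == "flat":
            base = rng.uniform(margin, 1 - margin)
            noiseless[i] = base
        elif lab == "up":
            base = rng.uniform(margin, 1 - margin - amp)
            noiseless[i] = base + amp * ramp
        else:
            base = rng.uniform(margin + amp, 1 - margin)
            noiseless[i] = base - amp * ramp
    noisy = np.clip(noiseless + rng.normal(0, config.noise_sd, noiseless.shape), 0, 1)
    index = [f"event_{i:04d}" for i in range(n_events)]
    return GroundTruth(
        dose_labels=config.dose_labels,
        psi_matrix=pd.DataFrame(noisy, index=index, columns=config.dose_labels),
        noiseless_psi=pd.DataFrame(noiseless, index=index, columns=config.dose_labels),
        cluster_labels=pd.Series(labels, index=index),
    )


def simulate_junction_counts(
    truth: GroundTruth,
    depth: float,
    seed: int = 0,
    event_type: str = "SE",
) -> pd.DataFrame:
    """Binomial inclusion/exclusion junction counts per event and dose.

    Per (event, dose) the total junction depth n is Poisson(``depth``), the
    inclusion count Binomial(n, psi), and the exclusion count n - inclusion.
    """
    if depth < 0:
        raise ConfigurationError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    psi = truth.psi_matrix
    rows = []
    for event in psi.index:
        for dose in psi.columns:
            n = int(rng.poisson(depth))
            k = int(rng.binomial(n, float(psi.loc[event, dose]))) if n else 0
            rows.append(
                {
                    "event_id": event,
                    "event_type": event_type,
                    "sample": dose,
                    "k_inc": k,
                    "k_exc": n - k,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CG read-through evidence
# ---------------------------------------------------------------------------

def _tx_junction_rows(gene: Gene) -> list[tuple[int, int]]:
    tx = gene.longest_transcript()
    return [(lo, hi) for lo, hi in tx.introns()]


def simulate_cg_readthrough(
    config: SimulationConfig,
    ann: GenomeAnnotation,
    seed: int | None = None,
    cg_pair_fraction: float = 0.5,
    downstream_expression_factor: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[PlantedCG]]:
    """Junction and coverage evidence with planted dose-dependent CGs.

    A random fraction of gene pairs is planted with a read-through junction
    from the upstream gene's penultimate-exon donor to the downstream gene's
    second-exon acceptor (the modal pattern).  Per dose, the upstream
    terminal junction's Poisson(depth) reads are split binomially by the
    dose's read-through rate: CG reads are taken *from* the wild-type
    terminal junction, so read-through grows at the canonical isoform's
    expense and total depth is conserved.  All other annotated junctions
    receive Poisson(depth) wild-type counts (scaled by
    ``downstream_expression_factor`` for downstream partners, which the
    study observed to be the less-expressed partner).  Coverage rows carry
    the mean depth of each gene's CG-retained and CG-removed portions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pair_ids = sorted({g[:-1] for g in ann.genes if g.endswith(("A", "B"))})
    pair_ids = [p for p in pair_ids if f"{p}A" in ann.genes and f"{p}B" in ann.genes]
    n_cg = int(round(cg_pair_fraction * len(pair_ids)))
    cg_pairs = set(rng.choice(pair_ids, size=n_cg, replace=False)) if n_cg else set()

    junction_rows = []
    coverage_rows = []
    planted: list[PlantedCG] = []
    for pid in pair_ids:
        up, dn = ann.genes[f"{pid}A"], ann.genes[f"{pid}B"]
        up_tx, dn_tx = up.longest_transcript(), dn.longest_transcript()
        is_cg = pid in cg_pairs
        donor = up_tx.exons[-2].end
        acceptor = dn_tx.exons[1].start
        if is_cg:
            planted.append(
                PlantedCG(up.id, dn.id, up.chrom, up.strand, donor, acceptor)
            )
        for d_idx, dose in enumerate(config.dose_labels):
            rate = config.cg_rate_curve[d_idx] if is_cg else 0.0
            # upstream gene: all junctions; the terminal one loses reads to CG
            up_juncs = _tx_junction_rows(up)
            for lo, hi in up_juncs[:-1]:
                n = int(rng.poisson(config.depth))
                junction_rows.append((up.chrom, "+", lo, hi, dose, n))
            n_term = int(rng.poisson(config.depth))
            k_cg = int(rng.binomial(n_term, rate)) if n_term else 0
            lo, hi = up_juncs[-1]
            junction_rows.append((up.chrom, "+", lo, hi, dose, n_term - k_cg))
            if k_cg > 0:
                junction_rows.append((up.chrom, "+", donor, acceptor, dose, k_cg))
            dn_depth = config.depth * downstream_expression_factor
            for lo, hi in _tx_junction_rows(dn):
                n = int(rng.poisson(dn_depth))
                junction_rows.append((dn.chrom, "+", lo, hi, dose, n))
            # coverage: removed portions carry only wild-type transcripts
            coverage_rows.append((up.id, "retained", dose, config.depth))
            coverage_rows.append((up.id, "removed", dose, config.depth * (1 - rate)))
            coverage_rows.append(
                (dn.id, "retained", dose, dn_depth + config.depth * rate)
            )
            coverage_rows.append((dn.id, "removed", dose, dn_depth))
    junctions = pd.DataFrame(
        junction_rows, columns=["chrom", "strand", "donor", "acceptor", "sample", "count"]
    )
    junctions = junctions[junctions["count"] > 0].reset_index(drop=True)
    coverage = pd.DataFrame(
        coverage_rows, columns=["feature_id", "region", "sample", "mean_depth"]
    )
    return junctions, coverage, planted


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def plant_motifs(
    genome: dict[str, str],
    spec: MotifPlantSpec,
    seed: int = 0,
    max_retries: int = 1000,
) -> dict[str, str]:
    """Write consensus occurrences into target intervals at a given density.

    ``round(density * length)`` non-overlapping copies are placed uniformly
    at random per interval; colliding draws are re-drawn up to
    ``max_retries`` times and then rejected as infeasible.  A density of 0
    leaves the sequence unchanged.  Requested occupancy above 1 is an error.
    """
    rng = np.random.default_rng(seed)
    consensus = spec.consensus.upper().replace("U", "T")
    mlen = len(consensus)
    out = {c: bytearray(s, "ascii") for c, s in genome.items()}
    for chrom, start, end in spec.intervals:
        length = end - start
        if mlen >= length:
            raise ConfigurationError("motif consensus longer than target region")
        n = int(round(spec.density * length))
        if n * mlen > length:
            raise ConfigurationError(
                f"requested density {spec.density} infeasible in {length} bp"
            )
        placed: list[int] = []
        for _ in range(n):
            for _attempt in range(max_retries):
                p = int(rng.integers(0, length - mlen + 1))
                if all(abs(p - q) >= mlen for q in placed):
                    placed.append(p)
                    break
            else:
                raise ConfigurationError(
                    f"could not place {n} motif copies in {length} bp"
                )
        for p in placed:
            out[chrom][start + p : start + p + mlen] = consensus.encode()
        if n > 0:
            _scrub_accidental(out[chrom], start, end, consensus, placed, rng)
    return {c: b.decode() for c, b in out.items()}


def _scrub_accidental(
    arr: bytearray, start: int, end: int, consensus: str, placed: list[int], rng
) -> None:
    """Mutate chance consensus occurrences so planted density stays exact."""
    mlen = len(consensus)
    target = consensus.encode()
    keep = set(placed)
    for _ in range(10):  # re-scan: a mutation could in principle create a hit
        dirty = False
        for p in range(end - start - mlen + 1):
            if p in keep:
                continue
            if any(abs(p - q) < mlen for q in keep):
                continue  # overlaps a planted copy; leave untouched
            if bytes(arr[start + p : start + p + mlen]) == target:
                mid = start + p + mlen // 2
                old = chr(arr[mid])
                choices = [b for b in "ACGT" if b != old and b != consensus[mlen // 2]]
                arr[mid] = ord(choices[int(rng.integers(0, len(choices)))])
                dirty = True
        if not dirty:
            return


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------

def simulate_long_reads(
    ann: GenomeAnnotation,
    planted_cgs: list[PlantedCG],
    jitter_bp: int = 0,
    reads_per_transcript: int = 1,
    reads_per_cg: int = 1,
    aligned_proportion: tuple[float, float] = (0.92, 1.0),
    identity: tuple[float, float] = (0.85, 1.0),
    seed: int = 0,
) -> list[LongRead]:
    """Long reads as junction chains from transcripts and planted CG isoforms.

    CG reads chain the upstream gene's junctions, the read-through junction
    and the downstream gene's junctions from the acceptor onward.  With
    ``jitter_bp`` > 0 every junction coordinate is displaced by a nonzero
    offset of at most that many bp, so exact-match validation must fail.
    Alignment attributes are drawn uniformly from the given ranges.
    """
    if jitter_bp < 0:
        raise ConfigurationError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    reads: list[LongRead] = []

    def jitter(juncs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        if jitter_bp == 0:
            return juncs
        out = []
        for lo, hi in juncs:
            d1 = int(rng.integers(1, jitter_bp + 1)) * int(rng.choice([-1, 1]))
            d2 = int(rng.integers(1, jitter_bp + 1)) * int(rng.choice([-1, 1]))
            out.append((lo + d1, hi + d2))
        return out

    def attrs() -> tuple[float, float]:
        return (
            float(rng.uniform(*aligned_proportion)),
            float(rng.uniform(*identity)),
        )

    i = 0
    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        tx = g.longest_transcript()
        for _ in range(reads_per_transcript):
            ap, ident = attrs()
            reads.append(
                LongRead(
                    id=f"read_{i:05d}",
                    chrom=g.chrom,
                    strand=g.strand,
                    junctions=jitter(tx.introns()),
                    aligned_proportion=ap,
                    identity=ident,
                )
            )
            i += 1
    for cg in planted_cgs:
        up_tx = ann.genes[cg.upstream_gene].longest_transcript()
        dn_tx = ann.genes[cg.downstream_gene].longest_transcript()
        lo, hi = (cg.donor, cg.acceptor) if cg.strand == "+" else (cg.acceptor, cg.donor)
        chain = [j for j in up_tx.introns() if j[1] <= lo]
        chain.append((lo, hi))
        chain.extend(j for j in dn_tx.introns() if j[0] >= hi)
        for _ in range(reads_per_cg):
            ap, ident = attrs()
            reads.append(
                LongRead(
                    id=f"read_{i:05d}",
                    chrom=cg.chrom,
                    strand=cg.strand,
                    junctions=jitter(chain),
                    aligned_proportion=ap,
                    identity=ident,
                )
            )
            i += 1
    return reads


# ---------------------------------------------------------------------------
# siRNA screen counts
# ---------------------------------------------------------------------------

def simulate_sirna_counts(
    n_cgs: int = 50,
    treatments: list[str] | None = None,
    n_controls: int = 10,
    effects: dict[str, list[str]] | None = None,
    fold: float = 5.0,
    mean_range: tuple[float, float] = (50.0, 200.0),
    cv: float = 0.2,
    libsize_range: tuple[float, float] = (0.7, 1.3),
    n_control_undetected: int = 0,
    seed: int = 0,
) -> "tuple[pd.DataFrame, SirnaCountTable]":
    """Control/treatment CG count tables with planted knockdown effects.

    Per-CG baseline means are uniform on ``mean_range``; per-library values
    are Gaussian around the baseline with coefficient of variation ``cv``
    (truncated at zero, rounded to counts) and multiplied by a per-library
    size factor so normalization is non-trivial.  Affected (treatment, CG)
    cells are shifted up by ``fold``.  ``n_control_undetected`` CGs are
    zeroed in every control library, populating the "detected in zero
    controls" group.
    """
    from .sirna_screen import SirnaCountTable

    if n_controls < 3:
        raise ConfigurationError("need >= 3 control libraries")
    rng = np.random.default_rng(seed)
    treatments = treatments if treatments is not None else [f"siRNA_{i:02d}" for i in range(8)]
    effects = effects or {}
    cg_ids = [f"CG{i:03d}" for i in range(n_cgs)]
    controls = [f"control_{i:02d}" for i in range(n_controls)]
    libraries = controls + list(treatments)
    mu = rng.uniform(*mean_range, size=n_cgs)
    factors = rng.uniform(*libsize_range, size=len(libraries))
    values = np.empty((n_cgs, len(libraries)))
    for j, lib in enumerate(libraries):
        draw = rng.normal(mu, cv * mu)
        if lib in effects:
            affected = [cg_ids.index(c) for c in effects[lib]]
            draw[affected] *= fold
        values[:, j] = np.maximum(draw, 0.0) * factors[j]
    values = np.round(values)
    if n_control_undetected:
        hidden = rng.choice(n_cgs, size=n_control_undetected, replace=False)
        for idx in hidden:
            values[idx, : n_controls] = 0.0
    counts = pd.DataFrame(values, index=cg_ids, columns=libraries)
    table = SirnaCountTable(counts=counts, control_libraries=controls)
    truth = pd.DataFrame(
        [
            {"treatment": t, "cg_id": c}
            for t, cgs in sorted(effects.items())
            for c in cgs
        ],
        columns=["treatment", "cg_id"],
    )
    return truth, table


# ---------------------------------------------------------------------------
# End-to-end study bundle
# ---------------------------------------------------------------------------

def simulate_study(
    config: SimulationConfig, outdir: str | os.PathLike | None = None
) -> dict:
    """Generate a full synthetic study and (optionally) write it to disk.

    Emits GTF + FASTA, the junction/coverage evidence with planted CGs, PSI
    event-count tables, long reads, an siRNA count table and the ground
    truth, plus a JSON manifest.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)
    ann, genome = simulate_annotation(config)
    truth = simulate_dose_response_profiles(
        config, n_events=2 * config.n_gene_pairs, seed=int(seeds[0])
    )
    event_counts = simulate_junction_counts(truth, config.depth, seed=int(seeds[1]))
    junctions, coverage, planted = simulate_cg_readthrough(
        config, ann, seed=int(seeds[2])
    )
    truth.planted_cgs = planted
    reads = simulate_long_reads(ann, planted, seed=int(seeds[3]))
    effects = {"siRNA_00": [f"CG{i:03d}" for i in range(5)]}
    sirna_truth, sirna_table = simulate_sirna_counts(
        effects=effects, seed=int(seeds[4])
    )
    truth.sirna_effects = effects
    bundle = {
        "annotation": ann,
        "genome": genome,
        "truth": truth,
        "event_counts": event_counts,
        "junctions": junctions,
        "coverage": coverage,
        "long_reads": reads,
        "sirna_table": sirna_table,
    }
    if outdir is not None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        write_annotation(ann, os.path.join(outdir, "annotation.gtf"))
        write_fasta(genome, os.path.join(outdir, "genome.fa"))
        event_counts.to_csv(os.path.join(outdir, "event_counts.tsv"), sep="\t", index=False)
        junctions.to_csv(os.path.join(outdir, "junctions.tsv"), sep="\t", index=False)
        coverage.to_csv(os.path.join(outdir, "coverage.tsv"), sep="\t", index=False)
        from .longread_validate import write_longread_table

        write_longread_table(reads, os.path.join(outdir, "long_reads.tsv"))
        sirna_table.to_tsv(os.path.join(outdir, "sirna_counts.tsv"))
        truth.write(os.path.join(outdir, "truth"))
        manifest = {
            "seed": config.seed,
            "n_gene_pairs": config.n_gene_pairs,
            "dose_grid": list(config.dose_grid),
            "files": sorted(os.listdir(outdir)),
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
    return bundle
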