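"""Percent-spliced-in (PSI) estimation, Bayes factors and event filtering.

The estimator is a junction-only beta-binomial model: only reads spanning the
junctions that discriminate the inclusion from the exclusion isoform are
counted, which makes isoform lengths irrelevant and keeps the posterior in
closed form.  With ``k_inc`` inclusion-junction reads and ``k_exc``
exclusion-junction reads and a uniform prior, the posterior over the
inclusion fraction psi is ``Beta(k_inc + 1, k_exc + 1)``.

Differential splicing between two samples is scored with an analytic Bayes
factor comparing the model in which the two samples have independent psi
values against the model in which they share one, both under uniform priors.
The binomial coefficients cancel, leaving a ratio of beta functions::

    BF = B(k1+1, n1-k1+1) * B(k2+1, n2-k2+1) / [B(1,1) * B(k1+k2+1, n1+n2-k1-k2+1)]

Events are retained for downstream analysis when BF >= 20, |dPSI| >= 0.1,
both isoforms have at least one supporting read, and each isoform is
supported by at least 10 reads across the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from .annotations import Exon, Gene, GenomeAnnotation, AnnotationError

__all__ = [
    "PSIEstimate",
    "DeltaASEvent",
    "IsoformPair",
    "estimate_psi",
    "bayes_factor_delta_psi",
    "filter_delta_as",
    "compare_samples",
    "build_cg_isoforms",
    "build_ri_isoforms",
    "read_event_counts",
    "write_delta_table",
]

EVENT_TYPES = ("SE", "RI", "A3SS", "A5SS", "AFE", "ALE", "MXE", "CG", "DI")


@dataclass(frozen=True)
class PSIEstimate:
    psi_mean: float
    ci_low: float
    ci_high: float
    k_inc: int
    k_exc: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.psi_mean <= self.ci_high <= 1.0):
            raise ValueError(f"inconsistent PSI estimate: {self}")


@dataclass
class DeltaASEvent:
    event_id: str
    event_type: str
    psi_1: PSIEstimate
    psi_2: PSIEstimate
    delta_psi: float = field(init=False)
    bayes_factor: float = field(init=False)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        self.delta_psi = self.psi_2.psi_mean - self.psi_1.psi_mean
        self.bayes_factor = bayes_factor_delta_psi(
            self.psi_1.k_inc,
            self.psi_1.k_inc + self.psi_1.k_exc,
            self.psi_2.k_inc,
            self.psi_2.k_inc + self.psi_2.k_exc,
        )


@dataclass
class IsoformPair:
    inclusion: list[Exon]
    exclusion: list[Exon]

    def __post_init__(self) -> None:
        if not self.inclusion or not self.exclusion:
            raise ValueError("isoform chains must be non-empty")


def estimate_psi(k_inc: int, k_exc: int) -> PSIEstimate:
    """Posterior PSI under the beta-binomial junction model.

    Mean ``(k_inc + 1) / (k_inc + k_exc + 2)`` with a central 95% credible
    interval from the Beta(k_inc+1, k_exc+1) posterior.
    """
    if k_inc < 0 or k_exc < 0:
        raise ValueError("read counts must be non-negative")
    a, b = k_inc + 1, k_exc + 1
    lo, hi = beta_dist.ppf([0.025, 0.975], a, b)
    return PSIEstimate(a / (a + b), float(lo), float(hi), k_inc, k_exc)


def bayes_factor_delta_psi(k1: int, n1: int, k2: int, n2: int) -> float:
    """Analytic Bayes factor: independent-psi over shared-psi marginal likelihood."""
    for k, n in ((k1, n1), (k2, n2)):
        if k < 0 or n < 0 or k > n:
            raise ValueError(f"invalid counts k={k}, n={n}")
    log_bf = (
        betaln(k1 + 1, n1 - k1 + 1)
        + betaln(k2 + 1, n2 - k2 + 1)
        - betaln(1, 1)
        - betaln(k1 + k2 + 1, n1 + n2 - k1 - k2 + 1)
    )
    return float(np.exp(log_bf))


def filter_delta_as(
    events: Sequence[DeltaASEvent],
    min_bf: float = 20.0,
    min_delta: float = 0.1,
    min_iso_reads: int = 10,
    per_isoform: bool = True,
) -> list[DeltaASEvent]:
    """Retain differential events passing the study's removal-rule complement.

    An event is kept iff its Bayes factor is >= ``min_bf``, |dPSI| >=
    ``min_delta``, both isoforms have > 0 supporting reads in the comparison,
    and (with ``per_isoform=True``, the default reading) each isoform is
    supported by >= ``min_iso_reads`` reads; ``per_isoform=False`` instead
    requires the total over both isoforms to reach the threshold.
    """
    kept = []
    for ev in events:
        inc = ev.psi_1.k_inc + ev.psi_2.k_inc
        exc = ev.psi_1.k_exc + ev.psi_2.k_exc
        if ev.bayes_factor < min_bf:
            continue
        if abs(ev.delta_psi) < min_delta:
            continue
        if inc == 0 or exc == 0:
            continue
        if per_isoform:
            if inc < min_iso_reads or exc < min_iso_reads:
                continue
        elif inc + exc < min_iso_reads:
            continue
        kept.append(ev)
    return kept


def compare_samples(
    counts: pd.DataFrame, control: str, treated: str
) -> list[DeltaASEvent]:
    """Build per-event comparisons from a long count table.

    ``counts`` columns: event_id, event_type, sample, k_inc, k_exc.  Events
    present in both samples are compared control -> treated, preserving the
    table's event order.
    """
    out = []
    by_sample = {
        s: df.set_index("event_id") for s, df in counts.groupby("sample")
    }
    if control not in by_sample or treated not in by_sample:
        raise ValueError(f"samples {control!r}/{treated!r} not both present")
    c, t = by_sample[control], by_sample[treated]
    for eid in counts["event_id"].drop_duplicates():
        if eid not in c.index or eid not in t.index:
            continue
        rc, rt = c.loc[eid], t.loc[eid]
        out.append(
            DeltaASEvent(
                event_id=eid,
                event_type=str(rc["event_type"]),
                psi_1=estimate_psi(int(rc["k_inc"]), int(rc["k_exc"])),
                psi_2=estimate_psi(int(rt["k_inc"]), int(rt["k_exc"])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Isoform construction
# ---------------------------------------------------------------------------

def build_cg_isoforms(
    cg,
    ann: GenomeAnnotation,
    intergenic_exons: Sequence[Exon] = (),
) -> IsoformPair:
    """Inclusion/exclusion isoforms for a conjoined-gene event.

    The inclusion (conjoined) isoform comprises the junction-adjacent exon of
    the upstream gene, any detected intergenic exons, and the junction-
    adjacent exon of the downstream gene.  The exclusion (wild-type) isoform
    comprises the donor-adjacent exon plus up to one following exon of the
    upstream gene, if one exists.  Donor and acceptor must sit on annotated
    exon boundaries of the reference transcripts.
    """
    up = ann.genes[cg.upstream_gene]
    dn = ann.genes[cg.downstream_gene]
    up_tx = up.longest_transcript()
    dn_tx = dn.longest_transcript()

    def three_prime(e: Exon, strand: str) -> int:
        return e.end if strand == "+" else e.start

    def five_prime(e: Exon, strand: str) -> int:
        return e.start if strand == "+" else e.end

    donor_exon = next(
        (e for e in up_tx.exons if three_prime(e, up.strand) == cg.donor), None
    )
    acceptor_exon = next(
        (e for e in dn_tx.exons if five_prime(e, dn.strand) == cg.acceptor), None
    )
    if donor_exon is None or acceptor_exon is None:
        raise AnnotationError(
            f"CG {cg.upstream_gene}->{cg.downstream_gene}: donor/acceptor not at "
            "annotated exon boundaries"
        )
    inclusion = [donor_exon, *intergenic_exons, acceptor_exon]
    i = up_tx.exons.index(donor_exon)
    exclusion = [donor_exon]
    if i + 1 < len(up_tx.exons):
        exclusion.append(up_tx.exons[i + 1])
    return IsoformPair(inclusion=inclusion, exclusion=exclusion)


def build_ri_isoforms(
    intron: tuple[int, int], transcript
) -> IsoformPair:
    """Retained-intron isoforms: exon-intron-exon block vs spliced exon pair."""
    lo, hi = intron
    flanks = None
    exons = sorted(transcript.exons, key=lambda e: e.start)
    for a, b in zip(exons, exons[1:]):
        if (a.end, b.start) == (lo, hi):
            flanks = (a, b)
            break
    if flanks is None:
        raise AnnotationError(
            f"intron {intron} does not match an exon gap of {transcript.id}"
        )
    a, b = flanks
    merged = Exon(a.chrom, a.start, b.end, a.strand)
    return IsoformPair(inclusion=[merged], exclusion=[a, b])


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def read_event_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"event_id", "event_type", "sample", "k_inc", "k_exc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event count table missing columns: {sorted(missing)}")
    return df


def delta_table(events: Sequence[DeltaASEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_name": [e.event_id for e in events],
            "event_type": [e.event_type for e in events],
            "sample1_posterior_mean": [e.psi_1.psi_mean for e in events],
            "sample1_ci_low": [e.psi_1.ci_low for e in events],
            "sample1_ci_high": [e.psi_1.ci_high for e in events],
            "sample2_posterior_mean": [e.psi_2.psi_mean for e in events],
            "sample2_ci_low": [e.psi_2.ci_low for e in events],
            "sample2_ci_high": [e.psi_2.ci_high for e in events],
            "diff": [e.delta_psi for e in events],
            "bayes_factor": [e.bayes_factor for e in events],
        }
    )


def write_delta_table(events: Sequence[DeltaASEvent], path) -> None:
    delta_table(events).to_csv(path, sep="\t", index=False)
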