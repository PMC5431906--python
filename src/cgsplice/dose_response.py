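"""Signed co-response network clustering of PSI (or expression) dose profiles.

Profiles are rows of a matrix over an ordered dose grid.  A signed weighted
adjacency ``a_ij = ((1 + cor_ij) / 2) ** beta`` is raised to a soft-threshold
power ``beta`` chosen for scale-free topology fit; the topological overlap
measure (TOM) turns the adjacency into a similarity; average-linkage
hierarchical clustering of ``1 - TOM`` with a static cut and a minimum module
size yields modules, close modules are merged on eigen-event correlation, and
members correlating < 0.75 with their module's eigen-event are left
unassigned.  The eigen-event is the first principal component of the
module's row-standardized profiles, oriented to follow the member average.

The module also provides the cross-dataset concordance machinery: Huber
robust regression slopes of each profile against the dose index and a
label-shuffling permutation test on the proportion of slope-sign-concordant
events, with p = (b + 1) / (m + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterResult",
    "PermutationTestResult",
    "DoseResponseClustering",
    "interpolate_missing",
    "select_soft_threshold",
    "cluster_profiles",
    "eigen_event",
    "event_type_enrichment",
    "robust_slope",
    "concordance_permutation_test",
    "signed_adjacency",
    "topological_overlap",
    "filter_expression_profiles",
]

UNASSIGNED = 0


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def interpolate_missing(
    matrix: pd.DataFrame,
    max_missing: int = 2,
    forbid_consecutive: bool = True,
) -> pd.DataFrame:
    """Fill small per-row gaps by linear interpolation; drop ineligible rows.

    Rows with more than ``max_missing`` missing values are dropped, as are
    rows with two consecutive missing values when ``forbid_consecutive`` is
    set.  Interior gaps are filled linearly between the nearest observed
    columns; edge gaps take the nearest observed value.
    """
    keep = []
    for idx, row in matrix.iterrows():
        isna = row.isna().to_numpy()
        if isna.all():
            continue
        if isna.sum() > max_missing:
            continue
        if forbid_consecutive and np.any(isna[:-1] & isna[1:]):
            continue
        keep.append(idx)
    out = matrix.loc[keep].copy()
    out = out.interpolate(axis=1, limit_direction="both")
    return out


def filter_expression_profiles(
    matrix: pd.DataFrame,
    min_value: float = 1.0,
    min_libraries: int = 4,
    min_fold_change: float = 2.0,
    control: str | None = None,
) -> pd.DataFrame:
    """Eligibility filter for expression (FPKM-like) profile clustering.

    Rows must reach ``min_value`` in at least ``min_libraries`` columns and
    show a fold change >= ``min_fold_change`` for at least one treated column
    relative to the control column (the first column by default).
    """
    control = control if control is not None else matrix.columns[0]
    enough = (matrix >= min_value).sum(axis=1) >= min_libraries
    base = matrix[control].replace(0, np.nan)
    treated = matrix.drop(columns=[control])
    fc = treated.div(base, axis=0)
    fold = (fc >= min_fold_change) | (fc <= 1.0 / min_fold_change)
    return matrix[enough & fold.any(axis=1)]


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray, index=None) -> np.ndarray:
    sd = x.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = list(index[bad]) if index is not None else bad.tolist()
        raise ValueError(f"zero-variance rows cannot be clustered: {names}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def signed_adjacency(matrix: np.ndarray, beta: int) -> np.ndarray:
    """Signed adjacency ((1 + cor) / 2) ** beta; cor=1 -> 1, cor=-1 -> 0."""
    cor = np.corrcoef(matrix)
    cor = np.clip(cor, -1.0, 1.0)
    return ((1.0 + cor) / 2.0) ** beta


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned TOM on a (signed) adjacency with unit diagonal."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over binned connectivity.

    Positive-slope fits (anti-scale-free) score 0; fewer than 3 populated
    bins score 0.
    """
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    centers = np.array(
        [k[which == i].mean() if freq[i] else np.nan for i in range(n_bins)]
    )
    ok = freq > 0
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(freq[ok] / freq.sum())
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - ss_res / ss_tot
    return -np.sign(slope) * r2


def select_soft_threshold(
    matrix: pd.DataFrame | np.ndarray,
    candidates: Sequence[int] = tuple(range(1, 31)),
    fit_target: float = 0.8,
    fallback_min: int = 21,
    plateau_step: float = 0.01,
) -> int:
    """Choose the soft-threshold power beta for the signed network.

    For each candidate beta the scale-free topology fit R^2 of the resulting
    connectivity distribution is computed; the chosen beta is the smallest at
    which R^2 exceeds ``fit_target`` and the R^2 curve's per-step increase
    has fallen below ``plateau_step``.  When the fit never reaches the
    target, a power above 20 is returned: the first candidate >=
    ``fallback_min`` at which the curve has plateaued, else ``fallback_min``.
    """
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if x.shape[0] < 50:
        raise ValueError("soft-threshold selection needs >= 50 profiles")
    index = matrix.index if isinstance(matrix, pd.DataFrame) else None
    z = _standardize_rows(x, index)
    candidates = sorted(candidates)
    fits = []
    for b in candidates:
        a = signed_adjacency(z, b)
        k = a.sum(axis=1) - 1.0
        fits.append(_scale_free_fit(k))
    fits = np.asarray(fits)
    prev = -np.inf
    for b, r2, prev_r2 in zip(candidates, fits, np.concatenate([[np.nan], fits[:-1]])):
        if r2 >= fit_target and not math.isnan(prev_r2) and r2 - prev_r2 < plateau_step:
            return b
    for b, r2, prev_r2 in zip(candidates, fits, np.concatenate([[np.nan], fits[:-1]])):
        if (
            b >= fallback_min
            and not math.isnan(prev_r2)
            and abs(r2 - prev_r2) < plateau_step
        ):
            return b
    return max(fallback_min, candidates[0])


# ---------------------------------------------------------------------------
# Eigen-events and clustering
# ---------------------------------------------------------------------------

def eigen_event(submatrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """First principal component of row-standardized member profiles.

    The component is sign-oriented to correlate positively with the member
    average and scaled to unit (sample) variance.
    """
    x = submatrix.to_numpy(dtype=float) if isinstance(submatrix, pd.DataFrame) else np.asarray(submatrix, float)
    if x.shape[0] < 2:
        raise ValueError("eigen-event needs >= 2 members")
    z = _standardize_rows(x)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    ev = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(ev - ev.mean(), mean_profile - mean_profile.mean()) < 0:
        ev = -ev
    sd = ev.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (rank-0) sub-matrix")
    return (ev - ev.mean()) / sd


@dataclass
class ClusterResult:
    """Module assignment of dose profiles; label 0 means unassigned."""

    labels: pd.Series
    eigen_events: dict[int, np.ndarray]
    soft_power: int
    merged_from: dict[int, list[int]] = field(default_factory=dict)
    member_correlations: pd.Series | None = None

    @property
    def clusters(self) -> list[int]:
        return sorted(self.eigen_events)

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])

    def summary(self) -> str:
        lines = [
            "Dose-response profile clustering",
            f"  soft-threshold power (beta): {self.soft_power}",
            f"  profiles: {len(self.labels)}  clusters: {len(self.clusters)}",
        ]
        for c in self.clusters:
            ev = self.eigen_events[c]
            direction = "increasing" if ev[-1] > ev[0] else "decreasing"
            lines.append(
                f"  cluster {c}: {int((self.labels == c).sum())} members, "
                f"eigen-event {direction}"
            )
        lines.append(f"  unassigned: {int((self.labels == UNASSIGNED).sum())}")
        return "\n".join(lines)

    def plot_profiles(self, matrix: pd.DataFrame, ax=None):
        """Standardized member profiles per cluster with eigen-events."""
        import matplotlib.pyplot as plt

        clusters = self.clusters
        fig, axes = plt.subplots(1, max(len(clusters), 1), squeeze=False)
        z = pd.DataFrame(
            _standardize_rows(matrix.to_numpy(float), matrix.index),
            index=matrix.index,
            columns=matrix.columns,
        )
        for ax_, c in zip(axes[0], clusters):
            for m in self.members(c):
                ax_.plot(z.loc[m].to_numpy(), color="0.6", lw=0.5)
            ax_.plot(self.eigen_events[c], color="red", lw=2)
            ax_.set_title(f"cluster {c}")
        return fig


def cluster_profiles(
    matrix: pd.DataFrame,
    beta: int,
    min_module_size: int = 25,
    merge_height: float = 0.2,
    member_min_cor: float = 0.75,
    cut_height: float = 0.99,
) -> ClusterResult:
    """Signed-network TOM clustering of dose profiles.

    Average-linkage hierarchical clustering on ``1 - TOM`` is cut statically
    at ``cut_height``; groups below ``min_module_size`` are unassigned.
    Modules whose eigen-events are closer than ``merge_height`` (1 - Pearson
    correlation) are merged, and members correlating below
    ``member_min_cor`` with their module's eigen-event are unassigned (the
    eigen-event is re-estimated until the retained membership is stable).
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < min_module_size:
        return ClusterResult(
            labels=pd.Series(UNASSIGNED, index=matrix.index),
            eigen_events={},
            soft_power=beta,
        )
    z = _standardize_rows(x, matrix.index)
    adjacency = signed_adjacency(z, beta)
    tom = topological_overlap(adjacency)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    link = average(squareform(dissim, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")

    labels = np.zeros(len(raw), dtype=int)
    next_id = 1
    module_rows: dict[int, np.ndarray] = {}
    for c in np.unique(raw):
        rows = np.flatnonzero(raw == c)
        if rows.size >= min_module_size:
            labels[rows] = next_id
            module_rows[next_id] = rows
            next_id += 1

    # merge close modules on eigen-event correlation
    merged_from: dict[int, list[int]] = {c: [c] for c in module_rows}
    changed = True
    while changed and len(module_rows) > 1:
        changed = False
        ids = sorted(module_rows)
        evs = {c: eigen_event(z[module_rows[c]]) for c in ids}
        best = None
        for a, b in itertools.combinations(ids, 2):
            d = 1.0 - float(np.corrcoef(evs[a], evs[b])[0, 1])
            if d < merge_height and (best is None or d < best[0]):
                best = (d, a, b)
        if best is not None:
            _, a, b = best
            module_rows[a] = np.concatenate([module_rows[a], module_rows[b]])
            merged_from[a] = merged_from[a] + merged_from.pop(b)
            del module_rows[b]
            changed = True

    # membership filter against the (re-estimated) eigen-event
    final_labels = np.zeros(len(raw), dtype=int)
    eigen_events: dict[int, np.ndarray] = {}
    provenance: dict[int, list[int]] = {}
    member_cor = np.full(len(raw), np.nan)
    out_id = 1
    for c in sorted(module_rows, key=lambda c: -module_rows[c].size):
        rows = module_rows[c]
        while True:
            if rows.size < 2:
                rows = np.array([], dtype=int)
                break
            ev = eigen_event(z[rows])
            cors = np.array([float(np.corrcoef(z[r], ev)[0, 1]) for r in rows])
            keep = cors >= member_min_cor
            if keep.all():
                member_cor[rows] = cors
                break
            rows = rows[keep]
        if rows.size >= min_module_size:
            final_labels[rows] = out_id
            eigen_events[out_id] = eigen_event(z[rows])
            provenance[out_id] = merged_from.get(c, [c])
            out_id += 1

    result = ClusterResult(
        labels=pd.Series(final_labels, index=matrix.index),
        eigen_events=eigen_events,
        soft_power=beta,
        merged_from=provenance,
        member_correlations=pd.Series(member_cor, index=matrix.index),
    )
    return result


class DoseResponseClustering:
    """Model object wrapping the signed-network clustering of a profile matrix.

    Parameters
    ----------
    matrix : DataFrame
        Rows are events (or genes), columns the ordered dose grid.
    event_types : Series, optional
        Event class per row, enabling per-cluster enrichment tests.
    """

    def __init__(self, matrix: pd.DataFrame, event_types: pd.Series | None = None):
        if matrix.shape[1] < 4:
            raise ValueError("need >= 4 dose columns")
        self.matrix = matrix
        self.event_types = event_types

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, id_col: str = "event_id", type_col: str | None = "event_type"
    ) -> "DoseResponseClustering":
        df = df.set_index(id_col)
        types = None
        if type_col and type_col in df.columns:
            types = df[type_col]
            df = df.drop(columns=[type_col])
        return cls(df.astype(float), types)

    def fit(
        self,
        beta: int | None = None,
        min_module_size: int = 25,
        merge_height: float = 0.2,
        member_min_cor: float = 0.75,
        cut_height: float = 0.99,
        max_missing: int = 2,
    ) -> ClusterResult:
        matrix = interpolate_missing(self.matrix, max_missing=max_missing)
        if beta is None:
            beta = select_soft_threshold(matrix)
        result = cluster_profiles(
            matrix,
            beta,
            min_module_size=min_module_size,
            merge_height=merge_height,
            member_min_cor=member_min_cor,
            cut_height=cut_height,
        )
        return result

    def enrichment(self, result: ClusterResult) -> pd.DataFrame:
        if self.event_types is None:
            raise ValueError("no event types supplied")
        bg = list(self.event_types.loc[result.labels.index])
        frames = []
        for c in result.clusters:
            members = result.members(c)
            sub = event_type_enrichment(
                list(self.event_types.loc[members]), bg, adjust=False
            )
            sub.insert(0, "cluster", c)
            frames.append(sub)
        out = pd.concat(frames, ignore_index=True)
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        return out


# ---------------------------------------------------------------------------
# Enrichment, robust slopes and the permutation test
# ---------------------------------------------------------------------------

def event_type_enrichment(
    cluster_types: Sequence[str],
    background_types: Sequence[str],
    adjust: bool = True,
) -> pd.DataFrame:
    """One-tailed hypergeometric over-representation of event types.

    For each type with K background members, drawing n = |cluster| events
    from N = |background| and observing x in the cluster, p = P(X >= x).
    """
    if len(cluster_types) == 0:
        raise ValueError("empty cluster")
    n_bg = len(background_types)
    n_cl = len(cluster_types)
    bg_counts = pd.Series(background_types).value_counts()
    cl_counts = pd.Series(cluster_types).value_counts()
    rows = []
    for typ, K in sorted(bg_counts.items()):
        x = int(cl_counts.get(typ, 0))
        p = float(hypergeom.sf(x - 1, n_bg, int(K), n_cl))
        rows.append({"event_type": typ, "cluster_count": x, "background_count": int(K), "p": p})
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def robust_slope(profile: Sequence[float], dose_axis: Sequence[float] | None = None) -> float:
    """Huber-loss robust regression slope of a profile over the dose axis.

    Iteratively reweighted least squares with Huber's T criterion (tuning
    constant 1.345) and MAD scale.  The dose axis defaults to the index of
    the dose in the ordered grid (0..k-1): only the slope sign is consumed
    downstream and any monotone re-axis preserves it.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 4:
        raise ValueError("need >= 4 points")
    x = (
        np.arange(y.size, dtype=float)
        if dose_axis is None
        else np.asarray(dose_axis, dtype=float)
    )
    if np.ptp(x) == 0:
        raise ValueError("zero-variance dose axis")
    if np.ptp(y) == 0:
        return 0.0
    exog = sm.add_constant(x)
    model = sm.RLM(y, exog, M=sm.robust.norms.HuberT(t=1.345))
    fit = model.fit(scale_est="mad", conv="coefs", tol=1e-8, maxiter=50)
    return float(fit.params[1])


@dataclass
class PermutationTestResult:
    proportion_concordant: float
    b: int
    m: int
    p: float
    n_pairs: int

    def __post_init__(self) -> None:
        assert 0.0 < self.p <= 1.0
        assert self.p >= 1.0 / (self.m + 1)


def _concordant_proportion(a: np.ndarray, b: np.ndarray) -> float | None:
    mask = (a != 0) & (b != 0)
    if not mask.any():
        return None
    return float(np.mean(np.sign(a[mask]) == np.sign(b[mask])))


def concordance_permutation_test(
    slopes_a: Sequence[float],
    slopes_b: Sequence[float],
    m: int = 10_000,
    seed: int | None = None,
    permutations: Sequence[Sequence[int]] | None = None,
) -> PermutationTestResult:
    """Label-shuffling test of slope-sign concordance between datasets.

    The observed statistic is the proportion of paired events whose robust
    slopes agree in sign (exact-zero slopes are excluded from the
    denominator).  The null is built by permuting the event labels of the
    second vector ``m`` times; ``b`` counts shuffles whose proportion reaches
    the observed one and p = (b + 1) / (m + 1).  ``permutations`` substitutes
    an explicit list of permutations (e.g., the exhaustive set) for the
    random draws.
    """
    a = np.asarray(slopes_a, dtype=float)
    bvec = np.asarray(slopes_b, dtype=float)
    if a.shape != bvec.shape:
        raise ValueError("slope vectors must be paired and equal length")
    obs = _concordant_proportion(a, bvec)
    if obs is None:
        raise ValueError("all slope pairs are sign ties; proportion undefined")
    if permutations is not None:
        perms = [np.asarray(p, dtype=int) for p in permutations]
    else:
        if m < 1:
            raise ValueError("need m >= 1 shuffles")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(a.size) for _ in range(m)]
    b_count = 0
    n_valid = 0
    for perm in perms:
        prop = _concordant_proportion(a, bvec[perm])
        if prop is None:
            continue
        n_valid += 1
        if prop >= obs:
            b_count += 1
    m_eff = n_valid
    p = (b_count + 1) / (m_eff + 1)
    return PermutationTestResult(
        proportion_concordant=obs,
        b=b_count,
        m=m_eff,
        p=p,
        n_pairs=int(((a != 0) & (bvec != 0)).sum()),
    )
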