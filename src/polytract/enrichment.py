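"""Locational enrichment statistics of genomic features within polytract territory.

The *territory* of a polytract subset is the merged set of genome positions
it occupies (optionally widened by one nucleotide per side).  For a genome
of N nucleotides and a territory of n nucleotides, a feature with M
instances of which k fall inside the territory is tested for
over-representation with the one-tailed binomial model

    p = P(X >= k),  X ~ Binomial(M, n/N)

and for under-representation with P(X <= k).  The effect size is the
relative risk RR = (k/M) / (n/N), the in-territory rate of the feature over
the territory's genomic occupancy rate, with a 95% confidence interval by
the Katz log method.  In *singleton* mode k and M count feature instances
(an instance overlapping the territory anywhere counts once); in *multiplex*
mode they count nucleotides.

An alternative published parameterization of the same test treats the
genome positions of the territory as the trials, X ~ Binomial(n, M/N); the
two differ numerically and the instance-based form is the default here
(``swap_roles=True`` selects the other).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .scanner import HingeRecord, PolytractRecord, extend_adjacency, merge_intervals

__all__ = [
    "Territory",
    "OverlapResult",
    "EnrichmentResult",
    "KSMatrix",
    "territory_from_tracts",
    "territory_from_hinges",
    "compute_overlap",
    "binom_p",
    "relative_risk",
    "hypergeom_embed_test",
    "embed_binomial_p",
    "bonferroni_flag",
    "rr_heatmap_impute",
    "ks_species_matrix",
    "length_density_correlation",
    "enrich",
]

Interval = tuple[str, int, int]


@dataclass
class Territory:
    """Merged nucleotide set occupied by a polytract subset.

    ``N`` is the genome size (all bases of the analyzed sequences, Ns
    included), ``n`` the territory size in nucleotides.  ``intervals`` maps
    chromosome to a disjoint sorted list of [start, end) pairs.
    """

    N: int
    n: int
    intervals: dict[str, list[tuple[int, int]]]
    seq_lengths: dict[str, int]
    extended: bool = False
    subset: str = "all"

    def __post_init__(self) -> None:
        total = sum(e - s for iv in self.intervals.values() for s, e in iv)
        if total != self.n:
            raise ValueError(f"territory size {self.n} != interval total {total}")
        if not 0 < self.n <= self.N:
            raise ValueError(f"need 0 < n <= N, got n={self.n}, N={self.N}")
        for chrom, iv in self.intervals.items():
            L = self.seq_lengths[chrom]
            prev = 0
            for s, e in iv:
                if not (prev <= s < e <= L):
                    raise ValueError(f"bad interval ({s}, {e}) on {chrom}")
                prev = e

    def contains(self, chrom: str, pos: int) -> bool:
        iv = self.intervals.get(chrom)
        if not iv:
            return False
        starts = np.array([s for s, _ in iv])
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < iv[i][1]


@dataclass(frozen=True)
class OverlapResult:
    """k of M feature units overlapping a territory (instances or nucleotides)."""

    mode: str
    k: int
    M: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.M:
            raise ValueError(f"need 0 <= k <= M, got k={self.k}, M={self.M}")


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    subset: str
    mode: str
    direction: str
    k: int
    M: int
    n: int
    N: int
    p: float
    RR: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass
class KSMatrix:
    """Pairwise two-sample Kolmogorov-Smirnov statistics with a dendrogram."""

    labels: list[str]
    D: np.ndarray
    linkage: np.ndarray = field(repr=False)


def _subset_tracts(
    tracts: Iterable[PolytractRecord],
    clades: Iterable[str] | None = None,
    species: Iterable[str] | None = None,
) -> list[PolytractRecord]:
    clades = set(clades) if clades is not None else None
    species = set(species) if species is not None else None
    return [
        t
        for t in tracts
        if (clades is None or t.clade in clades)
        and (species is None or t.species in species)
    ]


def territory_from_tracts(
    tracts: Sequence[PolytractRecord],
    seq_lengths: Mapping[str, int],
    clades: Iterable[str] | None = None,
    species: Iterable[str] | None = None,
    extend: bool = True,
    subset: str | None = None,
) -> Territory:
    """Territory of a clade/species subset of a polytract catalog.

    Adjacency extension (one nucleotide per side) is on by default and may
    be suppressed with ``extend=False``.
    """
    chosen = _subset_tracts(tracts, clades, species)
    if not chosen:
        raise ValueError("empty polytract subset: no territory")
    if extend:
        intervals = extend_adjacency(chosen, seq_lengths)
    else:
        grouped: dict[str, list[tuple[int, int]]] = {}
        for t in chosen:
            grouped.setdefault(t.chrom, []).append((t.start, t.end))
        intervals = {c: merge_intervals(iv) for c, iv in sorted(grouped.items())}
    n = sum(e - s for iv in intervals.values() for s, e in iv)
    label = subset or ",".join(sorted({t.clade for t in chosen}))
    return Territory(
        N=int(sum(seq_lengths.values())),
        n=int(n),
        intervals=intervals,
        seq_lengths=dict(seq_lengths),
        extended=extend,
        subset=label,
    )


def territory_from_hinges(
    hinges: Sequence[HingeRecord],
    seq_lengths: Mapping[str, int],
    extend: bool = False,
) -> Territory:
    """Territory of hinge sites (1 nt each); extension is off by default."""
    if not hinges:
        raise ValueError("no hinges: empty territory")
    grouped: dict[str, list[tuple[int, int]]] = {}
    for h in hinges:
        lo = max(0, h.pos - 1) if extend else h.pos
        hi = min(seq_lengths[h.chrom], h.pos + 2) if extend else h.pos + 1
        grouped.setdefault(h.chrom, []).append((lo, hi))
    intervals = {c: merge_intervals(iv) for c, iv in sorted(grouped.items())}
    n = sum(e - s for iv in intervals.values() for s, e in iv)
    return Territory(
        N=int(sum(seq_lengths.values())),
        n=int(n),
        intervals=intervals,
        seq_lengths=dict(seq_lengths),
        extended=extend,
        subset="hinge",
    )


def _coverage_before(
    starts: np.ndarray, ends: np.ndarray, cum: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Covered nucleotides in [0, x) for each x, given disjoint sorted intervals."""
    i = np.searchsorted(starts, x, side="right")
    cov = cum[i].astype(np.int64)
    has_prev = i > 0
    prev_end = np.where(has_prev, ends[np.maximum(i - 1, 0)], 0)
    cov -= np.maximum(prev_end - x, 0) * has_prev
    return cov


def compute_overlap(
    features: Sequence[Interval],
    territory: Territory,
    mode: str = "singleton",
) -> OverlapResult:
    """Count feature overlap with a territory.

    singleton: k = number of instances intersecting the territory by >= 1 nt,
    M = number of instances.  multiplex: k = total intersected nucleotides,
    M = total feature nucleotides.  Features extending past sequence bounds
    are clipped with a warning; an instance spanning several territory
    intervals still counts once in singleton mode.
    """
    if mode not in ("singleton", "multiplex"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    clipped = 0
    for chrom, start, end in features:
        L = territory.seq_lengths.get(chrom)
        if L is not None and (start < 0 or end > L):
            clipped += 1
            start, end = max(0, start), min(L, end)
        if end > start:
            per_chrom.setdefault(chrom, []).append((start, end))
    if clipped:
        warnings.warn(f"{clipped} feature(s) extended past sequence bounds; clipped")

    k = 0
    M = 0
    n_instances = 0
    for chrom, feats in per_chrom.items():
        a = np.array([s for s, _ in feats], dtype=np.int64)
        b = np.array([e for _, e in feats], dtype=np.int64)
        n_instances += len(feats)
        M += int((b - a).sum())
        iv = territory.intervals.get(chrom)
        if not iv:
            continue
        starts = np.array([s for s, _ in iv], dtype=np.int64)
        ends = np.array([e for _, e in iv], dtype=np.int64)
        cum = np.concatenate(([0], np.cumsum(ends - starts)))
        ov = _coverage_before(starts, ends, cum, b) - _coverage_before(
            starts, ends, cum, a
        )
        if mode == "singleton":
            k += int((ov > 0).sum())
        else:
            k += int(ov.sum())
    if mode == "singleton":
        M = n_instances
    return OverlapResult(mode=mode, k=k, M=M)


def binom_p(
    k: int,
    M: int,
    n: int,
    N: int,
    direction: str = "over",
    swap_roles: bool = False,
) -> float:
    """Exact binomial tail probability of the observed overlap.

    ``over``: P(X >= k); ``under``: P(X <= k); X ~ Binomial(M, n/N) by
    default.  ``swap_roles=True`` uses the alternative published
    parameterization X ~ Binomial(n, M/N) instead; the two are numerically
    different.  Exact tails, no normal approximation.
    """
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    if not 0 <= k <= M:
        raise ValueError(f"need 0 <= k <= M, got k={k}, M={M}")
    if not 0 < n <= N:
        raise ValueError(f"need 0 < n <= N, got n={n}, N={N}")
    trials, prob = (n, M / N) if swap_roles else (M, n / N)
    if direction == "over":
        return float(stats.binom.sf(k - 1, trials, prob))
    return float(stats.binom.cdf(k, trials, prob))


def relative_risk(k: int, M: int, n: int, N: int) -> tuple[float, float, float]:
    """Relative risk (k/M)/(n/N) with a Katz-log 95% confidence interval.

    SE(ln RR) = sqrt(1/k - 1/M + 1/n - 1/N).  For k = 0 the RR is 0 and the
    interval is unavailable (NaN bounds).
    """
    if M <= 0 or n <= 0:
        raise ValueError("need M > 0 and n > 0")
    rr = (k / M) / (n / N)
    if k == 0:
        return 0.0, math.nan, math.nan
    se = math.sqrt(1 / k - 1 / M + 1 / n - 1 / N)
    delta = 1.959963984540054 * se
    return rr, rr * math.exp(-delta), rr * math.exp(delta)


def hypergeom_embed_test(E: int, k_e: int, N: int, n: int) -> float:
    """Hypergeometric embedding test from four key numbers.

    ``E`` regions drawn (e.g. enhancers), ``k_e`` of them embedding at least
    one polytract, from a population of ``N`` genome nucleotides of which
    ``n`` are territory.  Returns P(X >= k_e) with X hypergeometric
    (population N, successes n, draws E).
    """
    if not 0 <= k_e <= E:
        raise ValueError(f"need 0 <= k_e <= E, got k_e={k_e}, E={E}")
    if E > N:
        raise ValueError(f"draws E={E} exceed population N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    return float(stats.hypergeom.sf(k_e - 1, N, n, E))


def embed_binomial_p(E: int, k_e: int, N: int, n: int, L: float) -> float:
    """Per-region binomial alternative to :func:`hypergeom_embed_test`.

    The hypergeometric form draws region *counts* from a population of
    *nucleotides*, mixing units.  This alternative treats each of the E
    regions (of typical length L nt) as one Bernoulli trial whose success
    probability is that a region embeds at least one territory nucleotide
    under uniform placement, q = 1 - (1 - n/N)^L, and returns P(X >= k_e)
    with X ~ Binomial(E, q).
    """
    if not 0 <= k_e <= E:
        raise ValueError(f"need 0 <= k_e <= E, got k_e={k_e}, E={E}")
    if L < 1:
        raise ValueError("region length must be >= 1")
    q = 1.0 - (1.0 - n / N) ** L
    return float(stats.binom.sf(k_e - 1, E, q))


def bonferroni_flag(
    pvals: Iterable[float],
    alpha: float = 0.01,
    m_tests: int = 1,
    threshold: float | None = None,
) -> np.ndarray:
    """Bonferroni significance flags: p < alpha / m_tests.

    ``threshold`` overrides the computed cutoff (e.g. a rounded family-wise
    policy such as 1e-4 for a ~100-feature landscape).
    """
    p = np.asarray(list(pvals), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    cut = threshold if threshold is not None else alpha / m_tests
    return p < cut


def rr_heatmap_impute(
    results: pd.DataFrame | Sequence[EnrichmentResult],
    direction: str = "over",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Reporting matrix of relative risks with insignificant cells imputed to 1.

    For the over-representation view, cells with RR < 1 or p > alpha are set
    to 1; for the under-representation view, cells with RR > 1 or p > alpha.
    Input is a DataFrame with columns feature, subset, RR, p (or a sequence
    of :class:`EnrichmentResult`); output is a feature x subset matrix.
    """
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [
                {"feature": r.feature, "subset": r.subset, "RR": r.RR, "p": r.p}
                for r in results
            ]
        )
    df = results.copy()
    if direction == "over":
        mask = (df["RR"] < 1) | (df["p"] > alpha)
    else:
        mask = (df["RR"] > 1) | (df["p"] > alpha)
    df.loc[mask, "RR"] = 1.0
    return df.pivot(index="feature", columns="subset", values="RR")


def ks_species_matrix(samples: Mapping[str, Sequence[float]]) -> KSMatrix:
    """Pairwise two-sample KS statistic matrix over per-species length samples.

    D[i, j] is the supremum ECDF difference between species i and j.  Rows
    of D are clustered hierarchically with one-minus-Pearson-correlation
    distance and average linkage.  Species with fewer than two observations
    are excluded with a warning.
    """
    kept: dict[str, np.ndarray] = {}
    for label in samples:
        arr = np.asarray(samples[label], dtype=float)
        if arr.size < 2:
            warnings.warn(f"species {label!r} has < 2 observations; excluded")
            continue
        kept[label] = arr
    labels = list(kept)
    if len(labels) < 2:
        raise ValueError("need at least two species with >= 2 observations")
    m = len(labels)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = stats.ks_2samp(kept[labels[i]], kept[labels[j]]).statistic
    dist = pdist(D, metric="correlation")
    if np.any(np.isnan(dist)):
        # one-minus-correlation is undefined for constant rows; define the
        # distance of such a pair as 0 when the rows are equal, else 1
        idx = np.triu_indices(m, k=1)
        equal = np.array([np.array_equal(D[i], D[j]) for i, j in zip(*idx)])
        dist = np.where(np.isnan(dist), np.where(equal, 0.0, 1.0), dist)
    Z = linkage(dist, method="average")
    return KSMatrix(labels=labels, D=D, linkage=Z)


def length_density_correlation(
    mean_lengths: Sequence[float], densities: Sequence[float]
) -> tuple[float, float]:
    """Pearson r between per-chromosome mean tract length and tract density,
    with the two-sided p-value for r != 0.

    Requires at least three chromosomes; zero variance in either variable
    gives (nan, nan) with a warning.
    """
    x = np.asarray(mean_lengths, dtype=float)
    y = np.asarray(densities, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired (mean length, density) observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined")
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def enrich(
    features: Sequence[Interval],
    territory: Territory,
    mode: str = "singleton",
    direction: str = "over",
    alpha: float = 0.01,
    m_tests: int = 1,
    feature_id: str = "feature",
    swap_roles: bool = False,
) -> EnrichmentResult:
    """Full enrichment test of one feature set against one territory."""
    ov = compute_overlap(features, territory, mode=mode)
    p = binom_p(ov.k, ov.M, territory.n, territory.N, direction, swap_roles=swap_roles)
    rr, lo, hi = relative_risk(ov.k, ov.M, territory.n, territory.N)
    sig = bool(bonferroni_flag([p], alpha=alpha, m_tests=m_tests)[0])
    return EnrichmentResult(
        feature=feature_id,
        subset=territory.subset,
        mode=mode,
        direction=direction,
        k=ov.k,
        M=ov.M,
        n=territory.n,
        N=territory.N,
        p=p,
        RR=rr,
        ci_low=lo,
        ci_high=hi,
        significant=sig,
    )
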