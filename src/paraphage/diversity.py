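"""Species-level diversity statistics.

Incidence-based (site = bacterial genome) species accumulation with the
exact hypergeometric expectation and variance, cluster-size/singleton
summaries, a two-sample Kolmogorov-Smirnov test, and the strict-vs-lenient
clustering comparison (size-distribution KS + refinement containment).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, kolmogorov

from .cluster import SpeciesPartition
from .errors import ParameterError


def build_incidence(partition: SpeciesPartition,
                    prophage_genomes: Mapping[str, str],
                    genomes: Optional[Sequence[str]] = None,
                    binary: bool = True) -> pd.DataFrame:
    """Genomes (sites) x species matrix from a partition.

    ``genomes`` optionally fixes the site set (e.g. to include genomes with
    no prophage); default is every genome that carries a member. Binary
    mode yields 0/1 incidence; otherwise member counts.
    """
    mm = partition.membership()
    rows: dict[str, Counter] = {}
    for pid, sp in mm.items():
        gid = prophage_genomes[pid]
        rows.setdefault(gid, Counter())[sp] += 1
    if genomes is None:
        genomes = sorted(rows)
    species = sorted(partition.species)
    df = pd.DataFrame(0, index=list(genomes), columns=species, dtype=int)
    for gid, counts in rows.items():
        if gid in df.index:
            for sp, c in counts.items():
                df.loc[gid, sp] = c
    if binary:
        df = df.gt(0).astype(int)
    return df


@dataclass
class AccumulationCurve:
    """Expected species richness vs number of genomes sampled.

    ``richness[i]`` is E[S_n] at ``n = n_sites[i]``; ``sd`` the analytic
    standard deviation; the CI bounds are ``richness +/- 1.96 sd``.
    """

    n_sites: np.ndarray
    richness: np.ndarray
    sd: np.ndarray

    @property
    def ci_low(self) -> np.ndarray:
        return self.richness - 1.96 * self.sd

    @property
    def ci_high(self) -> np.ndarray:
        return self.richness + 1.96 * self.sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_genomes": self.n_sites,
                "expected_richness": self.richness,
                "sd": self.sd,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _absent_prob(t_absent: np.ndarray, T: int, n: int) -> np.ndarray:
    """P(a species with ``T - t_absent`` incidences misses an n-site sample).

    ``t_absent`` = number of sites NOT containing the species; the
    probability is C(t_absent, n) / C(T, n), 0 when n > t_absent.
    Evaluated in log space (stable for thousands of sites).
    """
    t_absent = np.asarray(t_absent, dtype=float)
    out = np.zeros(t_absent.shape, dtype=float)
    ok = t_absent >= n
    out[ok] = np.exp(_log_choose(t_absent[ok], n) - _log_choose(T, n))
    return out


def accumulation_exact(incidence: pd.DataFrame | np.ndarray,
                       mode: str = "site",
                       abundance: Optional[pd.DataFrame] = None) -> AccumulationCurve:
    """Exact species accumulation curve.

    ``mode="site"`` (default): site-based expectation
    ``E[S_n] = S - sum_i C(T - T_i, n) / C(T, n)`` with the analytic
    variance of the hypergeometric formulation (joint absences from the
    pairwise co-incidence counts).

    ``mode="individual"``: the individual-based rarefaction variant mapped
    to sites — at n sites, richness is rarefied to ``m = round(n * N / T)``
    individuals using the abundance matrix (``abundance`` defaults to
    ``incidence`` when it already holds counts).
    """
    inc = np.asarray(incidence, dtype=int)
    if inc.ndim != 2 or inc.shape[0] < 1:
        raise ParameterError("incidence must be a sites x species matrix, T >= 1")
    T = inc.shape[0]
    binc = (inc > 0).astype(int)
    Ti = binc.sum(axis=0)
    keep = Ti >= 1
    binc = binc[:, keep]
    Ti = Ti[keep]
    S = Ti.shape[0]
    ns = np.arange(1, T + 1)
    if mode == "site":
        exp_s = np.empty(T, dtype=float)
        sds = np.empty(T, dtype=float)
        absent = T - Ti  # sites lacking species i
        joint_present = binc.T @ binc  # sites containing both i and j
        union = Ti[:, None] + Ti[None, :] - joint_present
        for idx, n in enumerate(ns):
            a_i = _absent_prob(absent, T, int(n))
            exp_s[idx] = S - a_i.sum()
            a_ij = _absent_prob(T - union, T, int(n))
            var = (a_i * (1.0 - a_i)).sum()
            cov = a_ij - np.outer(a_i, a_i)
            np.fill_diagonal(cov, 0.0)
            var += cov.sum()
            sds[idx] = math.sqrt(max(var, 0.0))
        return AccumulationCurve(n_sites=ns, richness=exp_s, sd=sds)
    if mode == "individual":
        ab = np.asarray(incidence if abundance is None else abundance, dtype=int)
        if ab.shape != inc.shape:
            raise ParameterError("abundance matrix shape must match incidence")
        Ni = ab.sum(axis=0)[keep]
        N = int(Ni.sum())
        exp_s = np.empty(T, dtype=float)
        sds = np.empty(T, dtype=float)
        for idx, n in enumerate(ns):
            m = int(round(n * N / T))
            m = min(max(m, 0), N)
            a_i = _absent_prob(N - Ni, N, m)
            exp_s[idx] = S - a_i.sum()
            # individual-based variance (independent-absence approximation
            # plus the multinomial covariance term of classic rarefaction)
            a_pair = np.zeros((S, S))
            for i in range(S):
                for j in range(i + 1, S):
                    both_absent = N - Ni[i] - Ni[j]
                    a_pair[i, j] = a_pair[j, i] = _absent_prob(
                        np.array([both_absent]), N, m
                    )[0]
            var = (a_i * (1.0 - a_i)).sum()
            cov = a_pair - np.outer(a_i, a_i)
            np.fill_diagonal(cov, 0.0)
            var += cov.sum()
            sds[idx] = math.sqrt(max(var, 0.0))
        return AccumulationCurve(n_sites=ns, richness=exp_s, sd=sds)
    raise ParameterError("mode must be 'site' or 'individual'")


def accumulation_montecarlo(incidence, n_draws: int = 10_000,
                            seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo accumulation curve from random site orderings.

    Returns mean richness and its standard error at every n; used as an
    independent cross-check of :func:`accumulation_exact`.
    """
    inc = (np.asarray(incidence, dtype=int) > 0)
    T = inc.shape[0]
    rng = np.random.default_rng(seed)
    rich = np.empty((n_draws, T), dtype=np.int32)
    for d in range(n_draws):
        order = rng.permutation(T)
        seen = np.logical_or.accumulate(inc[order], axis=0)
        rich[d] = seen.sum(axis=1)
    mean = rich.mean(axis=0)
    se = rich.std(axis=0, ddof=1) / math.sqrt(n_draws)
    return pd.DataFrame(
        {"n_genomes": np.arange(1, T + 1), "mean_richness": mean, "se": se}
    )


@dataclass(frozen=True)
class SingletonStats:
    n_species: int
    n_singletons: int
    singleton_fraction: float
    size_histogram: tuple[tuple[int, int], ...]  # (cluster size, frequency)


def singleton_stats(partition: SpeciesPartition) -> SingletonStats:
    """Singleton count/fraction and the cluster-size histogram."""
    sizes = partition.sizes()
    if not sizes:
        raise ParameterError("partition is empty")
    hist = Counter(sizes)
    n_single = hist.get(1, 0)
    return SingletonStats(
        n_species=len(sizes),
        n_singletons=n_single,
        singleton_fraction=n_single / len(sizes),
        size_histogram=tuple(sorted(hist.items())),
    )


def ks_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sample KS statistic: sup |F_x - F_y| over the pooled support."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    support = np.concatenate([x, y])
    fx = np.searchsorted(x, support, side="right") / x.size
    fy = np.searchsorted(y, support, side="right") / y.size
    return float(np.abs(fx - fy).max())


def ks_two_sample(x: Sequence[float], y: Sequence[float],
                  method: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    ``method="asymp"`` uses the asymptotic Kolmogorov distribution with
    effective size ``en = n_x n_y / (n_x + n_y)``:
    ``p = Q_KS(sqrt(en) * D)``. ``method="exact"`` enumerates every
    assignment of the pooled values into the two samples (only feasible for
    small inputs; intended for oracle checks).
    """
    d = ks_statistic(x, y)
    nx, ny = len(x), len(y)
    if method == "asymp":
        en = nx * ny / (nx + ny)
        p = float(kolmogorov(math.sqrt(en) * d))
        return d, min(max(p, 0.0), 1.0)
    if method == "exact":
        if nx + ny > 20:
            raise ParameterError("exact KS p only supported for nx + ny <= 20")
        pooled = list(x) + list(y)
        idx = range(nx + ny)
        count = 0
        total = 0
        for comb in combinations(idx, nx):
            sel = set(comb)
            xs = [pooled[i] for i in sel]
            ys = [pooled[i] for i in idx if i not in sel]
            total += 1
            if ks_statistic(xs, ys) >= d - 1e-12:
                count += 1
        return d, count / total
    raise ParameterError("method must be 'asymp' or 'exact'")


@dataclass
class ClusteringComparison:
    ks_D: float
    ks_p: float
    strict_stats: SingletonStats
    lenient_stats: SingletonStats
    mapping: dict[str, str]  # strict species -> lenient species (if refined)
    refinement_violations: list[str]

    @property
    def refinement_holds(self) -> bool:
        return not self.refinement_violations


def compare_clusterings(strict: SpeciesPartition,
                        lenient: SpeciesPartition) -> ClusteringComparison:
    """Compare a strict and a lenient clustering of the same sequences.

    Runs a KS test on the two cluster-size samples and checks refinement:
    every strict cluster must be contained in exactly one lenient cluster
    (the lenient graph is an edge superset, so strict species should only
    ever merge, not split).
    """
    if strict.all_ids != lenient.all_ids:
        raise ParameterError("the two partitions cover different id sets")
    d, p = ks_two_sample(strict.sizes(), lenient.sizes())
    lm = lenient.membership()
    mapping: dict[str, str] = {}
    violations: list[str] = []
    for name, members in strict.species.items():
        targets = {lm[m] for m in members}
        if len(targets) == 1:
            mapping[name] = next(iter(targets))
        else:
            violations.append(name)
    return ClusteringComparison(
        ks_D=d,
        ks_p=p,
        strict_stats=singleton_stats(strict),
        lenient_stats=singleton_stats(lenient),
        mapping=mapping,
        refinement_violations=sorted(violations),
    )
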