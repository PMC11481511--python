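"""Polylysogeny: prophage co-residence within bacterial genomes.

Per-genome prophage counts are compared across host categories and STs
with the Kruskal-Wallis rank test (always tie-corrected); divergence among
co-resident prophages is quantified by pairwise intra-genome ANI. In this
module ANI is expressed as a fraction in [0, 1] — symmetrized percent
identity divided by 100 — so a pooled mean of ~0.04 reads directly as
"co-resident prophages are almost entirely unalignable". Pairs with no
alignment contribute 0, and pooling is over pairs, not per-genome means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ani import AniMatrix
from .errors import JoinError, ParameterError
from .qc import ProphageRecord


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p: float


@dataclass
class IntraGenomeAni:
    """All unordered prophage pairs within one genome, as ANI fractions."""

    genome_id: str
    pairs: list[tuple[str, str, float]]

    @property
    def max_ani(self) -> float:
        return max(a for _, _, a in self.pairs)


def counts_per_genome(records: Iterable[ProphageRecord],
                      meta: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Table genome_id -> (n_prophages, host, st).

    Genomes present in ``meta`` but carrying no kept prophage are included
    with a count of zero.
    """
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.genome_id] = counts.get(rec.genome_id, 0) + 1
    if meta is not None:
        meta_idx = meta.set_index("genome_id")
        genomes = list(meta_idx.index)
        for g in counts:
            if g not in meta_idx.index:
                raise JoinError({g}, context="genome metadata")
        rows = [
            {
                "genome_id": g,
                "n_prophages": counts.get(g, 0),
                "host": meta_idx.loc[g].get("host"),
                "st": meta_idx.loc[g].get("st"),
            }
            for g in genomes
        ]
    else:
        rows = [
            {"genome_id": g, "n_prophages": n, "host": None, "st": None}
            for g, n in sorted(counts.items())
        ]
    return pd.DataFrame(rows, columns=["genome_id", "n_prophages", "host", "st"])


def group_medians(counts: pd.DataFrame, by: str = "host") -> pd.Series:
    """Median prophage count per group (rows with a missing group excluded)."""
    sub = counts.dropna(subset=[by])
    return sub.groupby(by)["n_prophages"].median()


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis H over two or more samples, with tie correction.

    ``H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)``, divided by
    ``1 - sum(t^3 - t)/(N^3 - N)`` for tie groups of size t; the p-value
    comes from the chi-square distribution with k-1 degrees of freedom.
    When all values across all groups are identical, H = 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ParameterError("kruskal_wallis needs at least two groups")
    if any(g.size == 0 for g in groups):
        raise ParameterError("every group needs at least one value")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    offset = 0
    for g in groups:
        r = ranks[offset:offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    denom = 1.0 - tie_term / (n_total ** 3 - n_total)
    df = len(groups) - 1
    if denom <= 0.0:  # every value identical
        return KruskalResult(H=0.0, df=df, p=1.0)
    h /= denom
    p = float(sps.chi2.sf(h, df))
    return KruskalResult(H=float(h), df=df, p=p)


def intra_genome_ani(records: Iterable[ProphageRecord],
                     matrix: AniMatrix):
    """Pairwise ANI between prophages sharing a genome.

    Returns ``(per_genome, mean, sd)``: a list of :class:`IntraGenomeAni`
    for every genome with two or more prophages, and the pooled mean and
    sample standard deviation over all pairs. ANI values are symmetrized
    identity fractions; an unalignable pair is 0, not missing.
    """
    by_genome: dict[str, list[str]] = {}
    for rec in records:
        by_genome.setdefault(rec.genome_id, []).append(rec.prophage_id)
    known = set(matrix.ids)
    missing = {
        pid for pids in by_genome.values() for pid in pids if pid not in known
    }
    if missing:
        raise JoinError(missing, context="ANI matrix")
    per_genome: list[IntraGenomeAni] = []
    pooled: list[float] = []
    for gid in sorted(by_genome):
        pids = sorted(by_genome[gid])
        if len(pids) < 2:
            continue
        pairs = []
        for a, b in combinations(pids, 2):
            ani = matrix.symmetrized_identity(a, b) / 100.0
            pairs.append((a, b, ani))
            pooled.append(ani)
        per_genome.append(IntraGenomeAni(genome_id=gid, pairs=pairs))
    if pooled:
        arr = np.asarray(pooled)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    else:
        mean, sd = math.nan, math.nan
    return per_genome, mean, sd


def intra_genome_frame(per_genome: Iterable[IntraGenomeAni]) -> pd.DataFrame:
    rows = [
        {"genome_id": g.genome_id, "prophage_a": a, "prophage_b": b, "ani": x}
        for g in per_genome
        for a, b, x in g.pairs
    ]
    return pd.DataFrame(rows, columns=["genome_id", "prophage_a", "prophage_b", "ani"])
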