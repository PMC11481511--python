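"""Host population structure of prophage species.

Joins the species partition with per-genome metadata (MLST sequence type,
7-locus allelic profile, host category, country) to quantify, per species:
host range over STs, mean pairwise allelic distance between those STs,
geographic dispersion over countries with Tukey outlier fences, and
cross-host ("hybrid") species. Members lacking an ST or country are
excluded from range counts but reported, mirroring the convention of
analysing "species assigned to STs" separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cluster import SpeciesPartition
from .errors import JoinError, ParameterError

HOST_CATEGORIES = ("human", "animal", "plant")


@dataclass(frozen=True)
class StProfile:
    """A Pasteur-scheme MLST sequence type: 7 allele numbers, None = missing."""

    st_id: str
    alleles: tuple[Optional[int], ...]

    def __post_init__(self):
        if len(self.alleles) != 7:
            raise ParameterError("an ST profile has exactly 7 allele slots")
        for a in self.alleles:
            if a is not None and a < 1:
                raise ParameterError("allele numbers are >= 1 (or None if missing)")

    @property
    def complete(self) -> bool:
        return all(a is not None for a in self.alleles)


def st_allelic_distance(a: StProfile, b: StProfile, with_excluded: bool = False):
    """Number of loci at which two ST profiles differ (0-7).

    Loci where either profile has a missing allele are excluded from the
    count; with ``with_excluded=True`` the return value is
    ``(distance, excluded_locus_indices)``.
    """
    dist = 0
    excluded = []
    for i, (x, y) in enumerate(zip(a.alleles, b.alleles)):
        if x is None or y is None:
            excluded.append(i)
        elif x != y:
            dist += 1
    if with_excluded:
        return dist, excluded
    return dist


def profiles_from_metadata(meta: pd.DataFrame) -> dict[str, StProfile]:
    """Extract one :class:`StProfile` per distinct ST from a metadata table."""
    out: dict[str, StProfile] = {}
    allele_cols = [f"allele_{i}" for i in range(1, 8)]
    for _, row in meta.iterrows():
        st = row.get("st")
        if _is_missing(st) or st in out:
            continue
        alleles = tuple(
            None if _is_missing(row.get(c)) else int(row[c]) for c in allele_cols
        )
        out[str(st)] = StProfile(st_id=str(st), alleles=alleles)
    return out


def mean_pairwise_allelic_distance(
    sts: Iterable[str], profiles: Mapping[str, StProfile]
) -> Optional[float]:
    """Mean allelic distance over all unordered pairs of distinct STs.

    None when fewer than two STs are given. High values indicate that the
    lineages carrying one prophage species are not closely related.
    """
    sts = sorted(set(sts))
    if len(sts) < 2:
        return None
    dists = [
        st_allelic_distance(profiles[a], profiles[b]) for a, b in combinations(sts, 2)
    ]
    return float(np.mean(dists))


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v == "" or (
        isinstance(v, str) and v.lower() in ("na", "nan", "none")
    )


def _genome_lookup(partition: SpeciesPartition,
                   prophage_genomes: Mapping[str, str],
                   meta: pd.DataFrame) -> pd.DataFrame:
    """Per-member table joining species, genome and metadata; validates ids."""
    mm = partition.membership()
    missing = set(mm) - set(prophage_genomes)
    if missing:
        raise JoinError(missing, context="prophage -> genome mapping")
    meta_idx = meta.set_index("genome_id")
    unknown = {g for g in (prophage_genomes[p] for p in mm) if g not in meta_idx.index}
    if unknown:
        raise JoinError(unknown, context="genome metadata")
    rows = []
    for pid, sp in mm.items():
        gid = prophage_genomes[pid]
        rec = meta_idx.loc[gid]
        rows.append(
            {
                "prophage_id": pid,
                "species": sp,
                "genome_id": gid,
                "st": None if _is_missing(rec.get("st")) else str(rec["st"]),
                "country": None if _is_missing(rec.get("country")) else str(rec["country"]),
                "host": None if _is_missing(rec.get("host")) else str(rec["host"]),
            }
        )
    return pd.DataFrame(rows)


def host_range(partition: SpeciesPartition,
               prophage_genomes: Mapping[str, str],
               meta: pd.DataFrame) -> pd.DataFrame:
    """Per-species ST host range.

    Columns: n_members, n_members_with_st, n_sts, sts (comma-joined),
    unassigned (True when no member has an ST). Counts exclude members
    lacking an ST.
    """
    tbl = _genome_lookup(partition, prophage_genomes, meta)
    rows = []
    for sp, grp in tbl.groupby("species", sort=False):
        sts = sorted({s for s in grp["st"] if s is not None})
        with_st = int(grp["st"].notna().sum())
        rows.append(
            {
                "species": sp,
                "n_members": len(grp),
                "n_members_with_st": with_st,
                "n_sts": len(sts),
                "sts": ",".join(sts),
                "unassigned": with_st == 0,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def geo_dispersion(partition: SpeciesPartition,
                   prophage_genomes: Mapping[str, str],
                   meta: pd.DataFrame) -> pd.DataFrame:
    """Per-species country dispersion (members without a country excluded)."""
    tbl = _genome_lookup(partition, prophage_genomes, meta)
    rows = []
    for sp, grp in tbl.groupby("species", sort=False):
        countries = sorted({c for c in grp["country"] if c is not None})
        with_country = int(grp["country"].notna().sum())
        rows.append(
            {
                "species": sp,
                "n_members": len(grp),
                "n_members_with_country": with_country,
                "n_countries": len(countries),
                "countries": ",".join(countries),
            }
        )
    return pd.DataFrame(rows).set_index("species")


@dataclass(frozen=True)
class TukeyFences:
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    outliers: tuple[float, ...]


def tukey_fences(values: Sequence[float]) -> TukeyFences:
    """Tukey's outlier fences using Tukey hinges (median-of-halves quartiles).

    For odd n the median belongs to both halves. Fences are
    ``Q1 - 1.5*IQR`` and ``Q3 + 1.5*IQR``; outliers fall strictly outside.
    """
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 0:
        raise ParameterError("tukey_fences needs at least one value")
    if n == 1:
        return TukeyFences(v[0], v[0], 0.0, v[0], v[0], ())

    def _median(x: list[float]) -> float:
        m = len(x)
        return x[m // 2] if m % 2 else (x[m // 2 - 1] + x[m // 2]) / 2.0

    half = n // 2
    lower_half = v[: half + (n % 2)]
    upper_half = v[half:]
    q1 = _median(lower_half)
    q3 = _median(upper_half)
    iqr = q3 - q1
    lo = q1 - 1.5 * iqr
    hi = q3 + 1.5 * iqr
    outliers = tuple(x for x in v if x < lo or x > hi)
    return TukeyFences(q1, q3, iqr, lo, hi, outliers)


def hybrid_host_species(partition: SpeciesPartition,
                        prophage_genomes: Mapping[str, str],
                        meta: pd.DataFrame) -> pd.DataFrame:
    """Species whose members come from two or more host categories.

    Returns one row per hybrid species with per-category member counts;
    members with no host assignment are not counted toward any category.
    """
    tbl = _genome_lookup(partition, prophage_genomes, meta)
    rows = []
    for sp, grp in tbl.groupby("species", sort=False):
        counts = grp["host"].dropna().value_counts().to_dict()
        if len(counts) >= 2:
            rows.append({"species": sp, **{c: counts.get(c, 0) for c in HOST_CATEGORIES}})
    return pd.DataFrame(rows, columns=["species", *HOST_CATEGORIES]).set_index("species") \
        if rows else pd.DataFrame(columns=["species", *HOST_CATEGORIES]).set_index("species")


def species_st_matrix(partition: SpeciesPartition,
                      prophage_genomes: Mapping[str, str],
                      meta: pd.DataFrame) -> pd.DataFrame:
    """Binary species x ST presence/absence matrix (ST-assigned members only)."""
    tbl = _genome_lookup(partition, prophage_genomes, meta)
    tbl = tbl[tbl["st"].notna()]
    if tbl.empty:
        return pd.DataFrame()
    return (
        pd.crosstab(tbl["species"], tbl["st"]).gt(0).astype(int)
    )


def species_summary(partition: SpeciesPartition,
                    prophage_genomes: Mapping[str, str],
                    meta: pd.DataFrame) -> pd.DataFrame:
    """Machine-readable per-species summary table.

    One row per species: member count, ST range, mean allelic distance
    between its STs, country range and host breakdown.
    """
    hr = host_range(partition, prophage_genomes, meta)
    geo = geo_dispersion(partition, prophage_genomes, meta)
    profiles = profiles_from_metadata(meta)
    tbl = _genome_lookup(partition, prophage_genomes, meta)
    host_counts = {
        sp: grp["host"].dropna().value_counts().to_dict()
        for sp, grp in tbl.groupby("species", sort=False)
    }
    out = hr.join(geo[["n_members_with_country", "n_countries", "countries"]])
    out["mean_allelic_distance"] = [
        mean_pairwise_allelic_distance(
            [s for s in row["sts"].split(",") if s], profiles
        )
        for _, row in out.iterrows()
    ]
    for cat in HOST_CATEGORIES:
        out[f"n_{cat}"] = [host_counts.get(sp, {}).get(cat, 0) for sp in out.index]
    return out
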