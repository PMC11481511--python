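"""Synthetic prophage communities with known species structure.

The generator emulates the empirical shape of a prophage collection drawn
from a clonally structured bacterial host population:

* unrelated random ancestors, one per species, 30-60 kb long, so that
  between-species nucleotide identity sits far below every clustering
  threshold while within-species members (mutants of one ancestor at ~1%
  divergence) sit far above it;
* a heavily skewed species-size distribution — most species are singletons,
  a few "cosmopolitan" species are very large;
* host-population structure: genomes carry an MLST sequence type (ST, a
  7-locus allelic profile), a host category (human/animal/plant) and a
  country; narrow species stay within one ST while cosmopolitan species are
  spread over a configured number of STs;
* superinfection exclusion by construction: no genome receives two members
  of the same species (toggleable).

Every output is a deterministic function of the configuration, including
its seed.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import decode, encode
from .errors import GenerationError, ParameterError

HOST_CATEGORIES = ("human", "animal", "plant")
_HOST_DETAIL = {
    "human": ("clinical", "carriage"),
    "animal": ("dog", "cattle", "bird", "pig"),
    "plant": ("grass", "soil-plant"),
}
_COUNTRY_POOL = (
    "MX", "US", "FR", "DE", "CN", "BR", "ZA", "AU",
    "IN", "GB", "ES", "IT", "JP", "CA", "AR", "TH",
)

PREDICTION_COLUMNS = (
    "prophage_id", "genome_id", "contig_id", "contig_length",
    "start", "end", "completeness",
)
METADATA_COLUMNS = (
    "genome_id", "st",
    *(f"allele_{i}" for i in range(1, 8)),
    "host", "host_detail", "country", "year",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic prophage community.

    ``fraction_singletons`` of the ``n_species`` are singletons; species
    listed in ``cosmopolitan_sizes`` are large and spread over
    ``cosmopolitan_st_spread`` distinct STs; every remaining species gets a
    size drawn uniformly from ``mid_size_range`` and is confined to one ST.
    """

    n_species: int = 40
    fraction_singletons: float = 0.72
    cosmopolitan_sizes: tuple[int, ...] = (25, 20)
    cosmopolitan_st_spread: tuple[int, ...] = (5, 4)
    mid_size_range: tuple[int, int] = (3, 7)
    within_species_divergence: float = 0.01
    within_species_indel_rate: float = 0.0005
    ancestor_length_range: tuple[int, int] = (30_000, 60_000)
    n_genomes: int = 80
    n_sts: int = 10
    st_profile_loci: int = 7
    host_mix: Mapping[str, float] = field(
        default_factory=lambda: {"human": 0.80, "animal": 0.15, "plant": 0.05}
    )
    n_countries: int = 8
    contig_flank: int = 5_000
    superinfection_exclusion: bool = True
    n_subthreshold: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ParameterError("n_species must be >= 1")
        if not 0.0 <= self.fraction_singletons <= 1.0:
            raise ParameterError("fraction_singletons must be in [0, 1]")
        for name in ("within_species_divergence", "within_species_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ParameterError(f"{name} must be in [0, 1)")
        if len(self.cosmopolitan_sizes) != len(self.cosmopolitan_st_spread):
            raise ParameterError(
                "cosmopolitan_sizes and cosmopolitan_st_spread must have equal length"
            )
        for size, spread in zip(self.cosmopolitan_sizes, self.cosmopolitan_st_spread):
            if spread < 1 or size < spread:
                raise ParameterError(
                    "each cosmopolitan species needs size >= st spread >= 1"
                )
        lo, hi = self.ancestor_length_range
        if lo < 1 or hi < lo:
            raise ParameterError("ancestor_length_range must be a positive interval")
        if abs(sum(self.host_mix.values()) - 1.0) > 1e-9:
            raise ParameterError("host_mix proportions must sum to 1")
        if not set(self.host_mix) <= set(HOST_CATEGORIES):
            raise ParameterError(f"host_mix keys must be among {HOST_CATEGORIES}")
        if self.n_sts < 1 or self.n_genomes < self.n_sts:
            raise ParameterError("need n_genomes >= n_sts >= 1")
        if self.n_countries < 1 or self.n_countries > len(_COUNTRY_POOL):
            raise ParameterError(f"n_countries must be in [1, {len(_COUNTRY_POOL)}]")
        if self.st_profile_loci != 7:
            raise ParameterError("the MLST scheme modelled here has exactly 7 loci")


@dataclass
class TruthTable:
    """Ground truth of a synthetic community.

    ``prophages`` maps prophage id -> (true species id, genome id);
    ``genomes`` maps genome id -> (st, country, host).
    """

    prophages: dict[str, tuple[str, str]]
    genomes: dict[str, tuple[str, str, str]]

    def species_of(self, prophage_id: str) -> str:
        return self.prophages[prophage_id][0]

    def labels(self, ids: Sequence[str]) -> list[str]:
        """True species labels in the order of ``ids``."""
        return [self.prophages[i][0] for i in ids]

    @property
    def n_species(self) -> int:
        return len({sp for sp, _ in self.prophages.values()})

    def species_st_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sp, gid in self.prophages.values():
            out.setdefault(sp, set()).add(self.genomes[gid][0])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "prophage_id": pid,
                "true_species": sp,
                "genome_id": gid,
                "st": self.genomes[gid][0],
                "country": self.genomes[gid][1],
                "host": self.genomes[gid][2],
            }
            for pid, (sp, gid) in self.prophages.items()
        ]
        return pd.DataFrame(rows, columns=[
            "prophage_id", "true_species", "genome_id", "st", "country", "host",
        ])


@dataclass
class SyntheticCommunity:
    """All outputs of :func:`generate_community`, cross-consistent by id."""

    config: SimConfig
    sequences: dict[str, str]
    predictions: pd.DataFrame
    metadata: pd.DataFrame
    truth: TruthTable

    def fasta(self) -> str:
        buf = io.StringIO()
        for pid, seq in self.sequences.items():
            buf.write(f">{pid}\n")
            for i in range(0, len(seq), 80):
                buf.write(seq[i:i + 80] + "\n")
        return buf.getvalue()

    def write(self, outdir) -> dict[str, str]:
        """Write FASTA + three TSV tables under ``outdir``; returns the paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "prophages.fasta"),
            "predictions": os.path.join(outdir, "predictions.tsv"),
            "metadata": os.path.join(outdir, "metadata.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        with open(paths["fasta"], "w") as fh:
            fh.write(self.fasta())
        self.predictions.to_csv(paths["predictions"], sep="\t", index=False)
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_ancestors(n: int, length_range: tuple[int, int], seed) -> list[str]:
    """``n`` independent uniform-random A/C/G/T sequences.

    Lengths are drawn uniformly from the closed ``length_range`` interval.
    Unrelatedness guarantees that chance identity between any two ancestors
    stays far below every ANI threshold used downstream.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ParameterError("length_range must be a positive interval")
    rng = _as_rng(seed)
    out = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append(decode(rng.integers(0, 4, length).astype(np.uint8)))
    return out


def mutate_sequence(seq: str, sub_rate: float, indel_rate: float, seed) -> str:
    """Mutate a sequence by per-site substitutions and geometric indels.

    Each site is substituted to a *different* base with probability
    ``sub_rate``; at each site, with probability ``indel_rate``, an insertion
    or deletion (equiprobable) of geometric length (mean 2, capped at 10) is
    applied. Deterministic under ``seed``.
    """
    if not seq:
        raise ParameterError("cannot mutate an empty sequence")
    for name, rate in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= rate < 1.0:
            raise ParameterError(f"{name} must be in [0, 1)")
    rng = _as_rng(seed)
    arr = encode(seq)
    if (arr > 3).any():
        raise ParameterError("sequence must contain only A/C/G/T")
    arr = arr.copy()
    n = arr.shape[0]
    mask = rng.random(n) < sub_rate
    k = int(mask.sum())
    if k:
        arr[mask] = (arr[mask] + rng.integers(1, 4, k).astype(np.uint8)) % 4
    if indel_rate > 0.0:
        sites = np.nonzero(rng.random(n) < indel_rate)[0]
        if sites.size:
            pieces = []
            prev = 0
            for p in sites:
                p = int(p)
                if p < prev:  # swallowed by a previous deletion
                    continue
                length = int(min(rng.geometric(0.5), 10))
                if rng.random() < 0.5:  # insertion before site p
                    pieces.append(arr[prev:p])
                    pieces.append(rng.integers(0, 4, length).astype(np.uint8))
                    prev = p
                else:  # deletion of [p, p+length)
                    pieces.append(arr[prev:p])
                    prev = p + length
            pieces.append(arr[prev:])
            arr = np.concatenate(pieces)
    return decode(arr)


def _species_plan(config: SimConfig, rng: np.random.Generator):
    """Species ids, sizes and ST spreads implied by the configuration."""
    n_singletons = int(round(config.fraction_singletons * config.n_species))
    n_cosmo = len(config.cosmopolitan_sizes)
    n_mid = config.n_species - n_cosmo - n_singletons
    if n_mid < 0:
        raise ParameterError(
            "n_species too small for the requested singleton fraction and "
            "cosmopolitan species"
        )
    lo, hi = config.mid_size_range
    sizes = (
        list(config.cosmopolitan_sizes)
        + [int(x) for x in rng.integers(lo, hi + 1, n_mid)]
        + [1] * n_singletons
    )
    spreads = list(config.cosmopolitan_st_spread) + [1] * (n_mid + n_singletons)
    ids = [f"S{i + 1:03d}" for i in range(config.n_species)]
    return ids, sizes, spreads


def generate_community(config: SimConfig) -> SyntheticCommunity:
    """Generate a full synthetic community from one configuration.

    Outputs: prophage sequences (dict id -> sequence), a CheckV-style
    prediction table, a genome metadata table with 7-locus ST profiles, and
    the :class:`TruthTable`. All four are cross-consistent and byte-stable
    under the configured seed.
    """
    rng = np.random.default_rng(config.seed)
    species_ids, sizes, spreads = _species_plan(config, rng)

    # --- host population -------------------------------------------------
    st_ids = [f"ST{i + 1}" for i in range(config.n_sts)]
    while True:
        profiles = rng.integers(1, 50, size=(config.n_sts, 7))
        if len({tuple(r) for r in profiles}) == config.n_sts:
            break
    countries = list(_COUNTRY_POOL[: config.n_countries])
    st_home_country = {st: countries[i % len(countries)] for i, st in enumerate(st_ids)}

    genome_ids = [f"G{i + 1:04d}" for i in range(config.n_genomes)]
    st_of_genome = np.resize(np.arange(config.n_sts), config.n_genomes)
    rng.shuffle(st_of_genome)
    cats = list(config.host_mix.keys())
    probs = np.array([config.host_mix[c] for c in cats], dtype=float)
    meta_rows = []
    for gid, st_idx in zip(genome_ids, st_of_genome):
        st = st_ids[int(st_idx)]
        host = cats[int(rng.choice(len(cats), p=probs))]
        detail = _HOST_DETAIL[host][int(rng.integers(0, len(_HOST_DETAIL[host])))]
        # STs are geographically confined: genomes carry their lineage's home
        # country except for occasional travel, so most species end up in one
        # or two countries while multi-ST species span several
        if rng.random() < 0.95:
            country = st_home_country[st]
        else:
            country = countries[int(rng.integers(0, len(countries)))]
        year = int(rng.integers(1985, 2024))
        meta_rows.append(
            {
                "genome_id": gid,
                "st": st,
                **{f"allele_{i + 1}": int(profiles[int(st_idx), i]) for i in range(7)},
                "host": host,
                "host_detail": detail,
                "country": country,
                "year": year,
            }
        )
    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    genomes_by_st: dict[str, list[str]] = {st: [] for st in st_ids}
    for gid, st_idx in zip(genome_ids, st_of_genome):
        genomes_by_st[st_ids[int(st_idx)]].append(gid)

    # --- species -> STs -> genomes ---------------------------------------
    ancestors = generate_ancestors(config.n_species, config.ancestor_length_range, rng)
    sequences: dict[str, str] = {}
    truth_prophages: dict[str, tuple[str, str]] = {}
    pred_rows = []
    for sp, size, spread, ancestor in zip(species_ids, sizes, spreads, ancestors):
        chosen = rng.choice(config.n_sts, size=spread, replace=False)
        chosen_sts = [st_ids[int(i)] for i in chosen]
        # round-robin over the chosen STs so every one of them is covered
        st_per_member = [chosen_sts[i % spread] for i in range(size)]
        member_genomes: list[str] = []
        if config.superinfection_exclusion:
            for st in chosen_sts:
                want = st_per_member.count(st)
                pool = genomes_by_st[st]
                if want > len(pool):
                    raise GenerationError(
                        f"species {sp}: needs {want} distinct genomes in {st} "
                        f"but only {len(pool)} exist (superinfection exclusion on)"
                    )
            for st in chosen_sts:
                want = st_per_member.count(st)
                pick = rng.choice(len(genomes_by_st[st]), size=want, replace=False)
                member_genomes.extend(genomes_by_st[st][int(i)] for i in pick)
        else:
            for st in st_per_member:
                pool = genomes_by_st[st]
                member_genomes.append(pool[int(rng.integers(0, len(pool)))])
        for k, gid in enumerate(member_genomes):
            pid = f"sim|{sp}|m{k + 1:02d}"
            seq = mutate_sequence(
                ancestor,
                config.within_species_divergence,
                config.within_species_indel_rate,
                rng,
            )
            sequences[pid] = seq
            truth_prophages[pid] = (sp, gid)
            flank = config.contig_flank
            start = flank // 2 + 1
            pred_rows.append(
                {
                    "prophage_id": pid,
                    "genome_id": gid,
                    "contig_id": f"{gid}_c{len(pred_rows) + 1}",
                    "contig_length": len(seq) + flank,
                    "start": start,
                    "end": start + len(seq) - 1,
                    "completeness": 100.0,
                }
            )

    # optional sub-threshold rows for exercising the QC filters
    for j in range(config.n_subthreshold):
        length = int(rng.integers(5_000, 15_000))
        seq = decode(rng.integers(0, 4, length).astype(np.uint8))
        pid = f"sim|LOWQ|m{j + 1:02d}"
        gid = genome_ids[int(rng.integers(0, len(genome_ids)))]
        sequences[pid] = seq
        low_completeness = float(rng.integers(5, 50))
        pred_rows.append(
            {
                "prophage_id": pid,
                "genome_id": gid,
                "contig_id": f"{gid}_lowq{j + 1}",
                "contig_length": length + 500,  # below the 30 kb contig rule
                "start": 251,
                "end": 250 + length,
                "completeness": low_completeness,
            }
        )

    predictions = pd.DataFrame(pred_rows, columns=list(PREDICTION_COLUMNS))
    truth_genomes = {
        r["genome_id"]: (r["st"], r["country"], r["host"]) for r in meta_rows
    }
    truth = TruthTable(prophages=truth_prophages, genomes=truth_genomes)
    return SyntheticCommunity(
        config=config,
        sequences=sequences,
        predictions=predictions,
        metadata=metadata,
        truth=truth,
    )


def config_from_dict(d: Mapping) -> SimConfig:
    """Build a :class:`SimConfig` from a plain mapping (e.g. parsed YAML)."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ParameterError(f"unknown SimConfig field(s): {sorted(unknown)}")
    kw = dict(d)
    for key in ("cosmopolitan_sizes", "cosmopolitan_st_spread", "mid_size_range",
                "ancestor_length_range"):
        if key in kw and kw[key] is not None:
            kw[key] = tuple(kw[key])
    return SimConfig(**kw)
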