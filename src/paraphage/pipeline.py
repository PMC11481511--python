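"""End-to-end orchestration: simulate/load -> qc -> ani -> cluster -> analyses.

A single :class:`PipelineConfig` (typically parsed from YAML) drives one
reproducible run; one seed governs every stochastic stage. The run
directory receives every artifact as tab-delimited text plus a
machine-readable ``summary.json`` with the headline quantities and stage
row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import ani, cluster, diversity, epi, polylysogeny, qc, synth
from .errors import PipelineConfigError

log = logging.getLogger("paraphage")


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (synthetic or files) and stage knobs."""

    outdir: str = "paraphage_run"
    seed: int = 0
    # either synthesize ...
    synth: Optional[dict] = field(default_factory=dict)
    # ... or read these files
    fasta: Optional[str] = None
    predictions: Optional[str] = None
    metadata: Optional[str] = None
    ani_identity: Optional[str] = None  # precomputed matrix pair (optional)
    ani_coverage: Optional[str] = None
    ani_scale: float = 1.0
    min_completeness: float = 50.0
    min_contig: int = 30_000
    ani_params: dict = field(default_factory=dict)
    cluster_params: dict = field(default_factory=dict)
    lenient_params: dict = field(
        default_factory=lambda: {"min_identity": 70.0, "min_coverage": 70.0}
    )
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self):
        if self.synth is None and (self.fasta is None or self.predictions is None):
            raise PipelineConfigError(
                "config needs either a 'synth' block or both 'fasta' and "
                "'predictions' paths"
            )
        if self.synth is None and self.metadata is None:
            raise PipelineConfigError(
                "config field 'metadata' is required when inputs are read from files"
            )
        for name in ("fasta", "predictions", "metadata", "ani_identity", "ani_coverage"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise PipelineConfigError(f"config field '{name}': no such file {path}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary dict (also written).

    Stage counts are conserved (predictions = kept + dropped; species member
    counts sum to kept prophages) and asserted before the summary is
    written. A repeated run with the same config is byte-identical.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # --- stage 0: inputs --------------------------------------------------
    truth = None
    if config.synth is not None:
        sim = synth.config_from_dict({**config.synth, "seed": config.seed})
        community = synth.generate_community(sim)
        community.write(os.path.join(config.outdir, "synth"))
        sequences = community.sequences
        predictions_df = community.predictions
        meta = community.metadata
        truth = community.truth
        log.info("synth: %d prophages, %d true species",
                 len(sequences), truth.n_species)
    else:
        sequences = ani._coerce_sequences(config.fasta)
        predictions_df = pd.read_csv(config.predictions, sep="\t")
        meta = pd.read_csv(config.metadata, sep="\t")
    summary["n_predictions"] = int(len(predictions_df))

    # --- stage 1: qc ------------------------------------------------------
    import io as _io

    buf = _io.StringIO()
    predictions_df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    records = qc.parse_predictions(buf)
    kept_raw, dropped = qc.filter_predictions(
        records, config.min_completeness, config.min_contig
    )
    if len(kept_raw) + len(dropped) != len(records):
        raise RuntimeError("qc filter stage lost records")
    kept, contig_report = qc.resolve_multicontig(kept_raw)
    summary["n_kept"] = len(kept)
    summary["n_dropped"] = len(dropped)
    summary["n_contigs_resolved"] = len(contig_report)
    qc.records_to_frame(kept).to_csv(
        os.path.join(config.outdir, "kept_prophages.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"prophage_id": r.prophage_id, "reasons": "; ".join(reasons)}
            for r, reasons in dropped
        ]
    ).to_csv(os.path.join(config.outdir, "dropped_prophages.tsv"), sep="\t", index=False)
    log.info("qc: kept %d / dropped %d of %d predictions",
             len(kept), len(dropped), len(records))

    kept_ids = [r.prophage_id for r in kept]
    kept_seqs = {pid: sequences[pid] for pid in kept_ids if pid in sequences}
    prophage_genomes = {r.prophage_id: r.genome_id for r in kept}

    # --- stage 2: ani -----------------------------------------------------
    if config.ani_identity is not None:
        matrix = ani.AniMatrix.from_tsv(
            config.ani_identity, config.ani_coverage, scale=config.ani_scale
        )
    else:
        matrix = ani.compute_ani_matrix(kept_seqs, ani.AniParams(**config.ani_params))
        matrix.to_tsv(os.path.join(config.outdir, "ani"))
    log.info("ani: %d x %d matrix", len(matrix.ids), len(matrix.ids))

    # --- stage 3: clustering ----------------------------------------------
    cp = cluster.ClusterParams(**config.cluster_params)
    graph = cluster.build_graph(matrix, cp)
    partition = cluster.name_species(
        cluster.paraclique_partition(graph, cp.glom, params=cp), cp.prefix
    )
    partition.to_frame().to_csv(
        os.path.join(config.outdir, "species.tsv"), sep="\t", index=False
    )
    sstats = diversity.singleton_stats(partition)
    summary["n_species"] = sstats.n_species
    summary["n_singletons"] = sstats.n_singletons
    summary["singleton_fraction"] = round(sstats.singleton_fraction, 6)
    assert sum(partition.sizes()) == len(kept_seqs), "species members != kept prophages"

    meta_idx = meta.set_index("genome_id")
    node_attrs = {}
    for pid in matrix.ids:
        gid = prophage_genomes.get(pid)
        if gid is not None and gid in meta_idx.index:
            row = meta_idx.loc[gid]
            node_attrs[pid] = {
                "genome": gid,
                "st": row.get("st", ""),
                "host": row.get("host", ""),
                "country": row.get("country", ""),
            }
    cluster.export_network(
        partition, graph, node_attrs, os.path.join(config.outdir, "network")
    )
    violations = cluster.check_superinfection_exclusion(partition, prophage_genomes)
    summary["superinfection_violations"] = len(violations)

    lenient_kwargs = {**config.lenient_params}
    lp = cluster.ClusterParams(**lenient_kwargs)
    lenient = cluster.name_species(
        cluster.paraclique_partition(cluster.build_graph(matrix, lp), lp.glom, params=lp),
        lp.prefix,
    )
    comparison = diversity.compare_clusterings(partition, lenient)
    summary["n_species_lenient"] = comparison.lenient_stats.n_species
    summary["size_distribution_ks_D"] = round(comparison.ks_D, 6)
    summary["refinement_holds"] = comparison.refinement_holds

    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        ids = sorted(kept_seqs)
        ari = adjusted_rand_score(truth.labels(ids), partition.labels(ids))
        summary["n_true_species"] = truth.n_species
        summary["species_recovery_ari"] = round(float(ari), 6)

    # --- stage 4: host range / geography ----------------------------------
    species_tbl = epi.species_summary(partition, prophage_genomes, meta)
    species_tbl.to_csv(os.path.join(config.outdir, "species_summary.tsv"), sep="\t")
    assigned = species_tbl[~species_tbl["unassigned"]]
    summary["n_species_with_st"] = int(len(assigned))
    summary["n_species_single_st"] = int((assigned["n_sts"] == 1).sum())
    fences = epi.tukey_fences(species_tbl["n_countries"].tolist())
    summary["country_upper_fence"] = fences.upper
    summary["median_countries_per_species"] = float(
        species_tbl["n_countries"].median()
    )
    st_matrix = epi.species_st_matrix(partition, prophage_genomes, meta)
    st_matrix.to_csv(os.path.join(config.outdir, "species_by_st.tsv"), sep="\t")

    # --- stage 5: polylysogeny --------------------------------------------
    counts = polylysogeny.counts_per_genome(kept, meta)
    counts.to_csv(os.path.join(config.outdir, "prophages_per_genome.tsv"),
                  sep="\t", index=False)
    host_groups = [
        grp["n_prophages"].to_numpy()
        for _, grp in counts.dropna(subset=["host"]).groupby("host")
    ]
    if len(host_groups) >= 2:
        kw = polylysogeny.kruskal_wallis(host_groups)
        summary["host_kruskal_H"] = round(kw.H, 6)
        summary["host_kruskal_p"] = kw.p
    per_genome, ani_mean, ani_sd = polylysogeny.intra_genome_ani(kept, matrix)
    polylysogeny.intra_genome_frame(per_genome).to_csv(
        os.path.join(config.outdir, "intra_genome_ani.tsv"), sep="\t", index=False
    )
    summary["intra_genome_ani_mean"] = round(ani_mean, 6)
    summary["intra_genome_ani_sd"] = round(ani_sd, 6)

    # --- stage 6: diversity -----------------------------------------------
    incidence = diversity.build_incidence(partition, prophage_genomes)
    curve = diversity.accumulation_exact(incidence)
    curve.to_frame().to_csv(
        os.path.join(config.outdir, "accumulation_curve.tsv"), sep="\t", index=False
    )
    summary["accumulation_final_richness"] = float(curve.richness[-1])

    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
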