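"""End-to-end orchestration: simulate/load -> differential -> CNA ->
bimodal integration -> networks -> enrichment, with a reproducible run
manifest.

Every stage writes its table under the output directory; the manifest
records the configuration, the per-stage counts and the SHA-256 of every
file written, so two runs with the same configuration and inputs can be
compared by hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cna as cna_mod
from . import differential as diff_mod
from . import enrichment as enrich_mod
from . import integration as integ_mod
from . import io as ohio
from . import network as net_mod
from .containers import OmicsMatrix
from .simulate import MECHANISMS, Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a full run; mirrors the per-module defaults."""

    out_dir: str = "omicshub_run"
    seed: int = 0
    simulate: CohortConfig | None = None
    inputs: dict = field(default_factory=dict)  # paths; see io module readers
    gmt: str | None = None
    fc_min: float = 2.0
    p_max: float = 0.01
    min_algorithms: int = 3
    r_max: float = -0.1
    pair_p_max: float = 0.05
    cna_r_min: float = 0.5
    cna_p_max: float = 0.05
    score_min: float = 0.4
    hub_k: int = 10
    recur_q_max: float = 0.01
    enrich_p_max: float = 0.05
    call_thresholds: cna_mod.CallThresholds = field(default_factory=cna_mod.CallThresholds)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("simulate"), dict):
            raw["simulate"] = CohortConfig(**raw["simulate"])
        if isinstance(raw.get("call_thresholds"), dict):
            raw["call_thresholds"] = cna_mod.CallThresholds(**raw["call_thresholds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunResult:
    cohort: Cohort | None
    gene_de: pd.DataFrame
    mirna_de: pd.DataFrame
    meth_de: pd.DataFrame
    recurrent: pd.DataFrame
    candidate_sets: integ_mod.CandidateGeneSets
    overlap: dict
    functional: pd.DataFrame
    centrality_tables: dict
    hubs_by_network: dict
    cross_degree: pd.DataFrame
    hub_table: pd.DataFrame
    enrichment: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig) -> Cohort:
    paths = config.inputs
    required = ["expression", "mirna", "methylation", "sample_meta", "site_to_gene",
                "segments", "genes", "targets", "ppi_edges"]
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValueError(f"inputs missing keys: {missing} (or provide a simulate block)")
    meta_path = paths["sample_meta"]
    return Cohort(
        expression=ohio.read_matrix(paths["expression"], meta_path),
        mirna=ohio.read_matrix(paths["mirna"], meta_path),
        methylation=ohio.read_matrix(paths["methylation"], meta_path),
        site_to_gene=ohio.read_site_map(paths["site_to_gene"]),
        segments=ohio.read_seg(paths["segments"]),
        genes=ohio.read_gene_table(paths["genes"]),
        targets=ohio.read_target_map(paths["targets"]),
        ppi_edges=ohio.read_edge_list(paths["ppi_edges"]),
        truth=None,
        config=None,
    )


def run(config: RunConfig) -> RunResult:
    """Execute every stage in dependency order and write all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
        written.append(path)

    # stage: cohort ----------------------------------------------------------
    sim = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        cohort = generate_cohort(sim)
    else:
        cohort = _load_inputs(config)
    logger.info("cohort: %d genes x %d samples", *cohort.expression.values.shape)

    # stage: differential ----------------------------------------------------
    gene_de = diff_mod.paired_moderated_test(
        cohort.expression, log_transform=True, fc_min=config.fc_min, p_max=config.p_max
    )
    mirna_de = diff_mod.paired_moderated_test(
        cohort.mirna, log_transform=True, fc_min=config.fc_min, p_max=config.p_max
    )
    meth_gene = diff_mod.aggregate_probes_to_genes(cohort.methylation, cohort.site_to_gene)
    meth_de = diff_mod.paired_moderated_test(
        meth_gene, log_transform=True, pseudocount=0.0, fc_min=config.fc_min, p_max=config.p_max
    )
    save(gene_de, "differential_genes.tsv")
    save(mirna_de, "differential_mirnas.tsv")
    save(meth_de, "differential_methylation.tsv")
    deg_up, deg_down = diff_mod.status_sets(gene_de)
    logger.info("DEGs: %d up, %d down; DE miRNAs: %d; DM genes: %d",
                len(deg_up), len(deg_down),
                int((mirna_de["status"] != "ns").sum()), int((meth_de["status"] != "ns").sum()))

    # stage: copy number -----------------------------------------------------
    ratios = cna_mod.map_segments_to_genes(cohort.segments, cohort.genes)
    calls = cna_mod.call_states(ratios, config.call_thresholds)
    recurrent = cna_mod.recurrent_genes(calls, q_max=config.recur_q_max)
    save(calls, "cna_calls.tsv")
    save(recurrent, "cna_recurrent.tsv", index=False)
    amplified, deleted = cna_mod.recurrent_sets(recurrent)

    # stage: integration -----------------------------------------------------
    targets = integ_mod.filter_targets(cohort.targets, config.min_algorithms)
    mirna_pairs, mirna_set = integ_mod.mirna_bimodal_filter(gene_de, mirna_de, targets)
    if len(mirna_pairs):
        records = integ_mod.correlate(mirna_pairs, cohort.mirna, cohort.expression)
    else:
        records = pd.DataFrame(columns=["id_a", "id_b", "r", "p", "n"])
    functional = integ_mod.functional_pairs(records, config.r_max, config.pair_p_max)
    meth_ann, meth_set = integ_mod.methylation_bimodal_filter(gene_de, meth_de)
    cna_ann, cna_set = integ_mod.cna_bimodal_filter(
        gene_de, amplified, deleted, cohort.expression, ratios,
        r_min=config.cna_r_min, p_max=config.cna_p_max,
    )
    sets = integ_mod.build_candidate_sets(mirna_pairs, mirna_set, gene_de, meth_ann, meth_set, cna_ann, cna_set)
    overlap = integ_mod.overlap_analysis(sets)
    save(mirna_pairs, "candidates_mirna_pairs.tsv", index=False)
    save(sets.mirna_annotations, "candidates_mirna.tsv", index=False)
    save(meth_ann, "candidates_methylation.tsv", index=False)
    save(cna_ann, "candidates_cna.tsv", index=False)
    save(functional, "functional_pairs.tsv", index=False)
    save_json(overlap, "candidate_overlap.json")

    # stage: networks --------------------------------------------------------
    degs = deg_up | deg_down
    graph = net_mod.build_deg_network(cohort.ppi_edges, degs, config.score_min)
    centrality_tables: dict[str, pd.DataFrame] = {}
    hubs_by_network: dict[str, pd.DataFrame] = {}
    subnet_sizes: dict[str, dict] = {}
    for mech, seed_set in zip(MECHANISMS, (sets.mirna_set, sets.meth_set, sets.cna_set)):
        sub = net_mod.extract_subnetwork(graph, seed_set)
        subnet_sizes[mech] = {"nodes": sub.number_of_nodes(), "edges": sub.number_of_edges()}
        if sub.number_of_nodes() == 0:
            continue
        table = net_mod.centralities(sub)
        centrality_tables[mech] = table
        hubs_by_network[mech] = net_mod.hub_call(table, seed_set, k=config.hub_k)
        save(table, f"centrality_{mech}.tsv")
        save(hubs_by_network[mech], f"hubs_{mech}.tsv")
    all_candidates = sets.mirna_set | sets.meth_set | sets.cna_set
    already = {g for t in hubs_by_network.values() for g in t.index}
    if len(centrality_tables) >= 2:
        cross = net_mod.cross_network_degree_rule(
            centrality_tables, all_candidates, k=config.hub_k, exclude=already
        )
    else:
        cross = pd.DataFrame(columns=["gene_id", "networks", "n_networks"]).set_index("gene_id")
    hub_table = net_mod.hub_report(hubs_by_network, cross, sets, gene_de)
    save(cross, "cross_network_key_genes.tsv")
    save(hub_table, "key_genes.tsv")

    # stage: enrichment --------------------------------------------------------
    if config.gmt:
        collection = enrich_mod.read_gmt(config.gmt)
        background = set(cohort.expression.feature_ids)
        enriched = enrich_mod.enrich(all_candidates & background, background, collection, config.enrich_p_max)
    else:
        enriched = enrich_mod.empty_result()
    save(enriched, "enrichment.tsv", index=False)

    # manifest -----------------------------------------------------------------
    summary = {
        "n_deg_up": len(deg_up),
        "n_deg_down": len(deg_down),
        "n_de_mirnas": int((mirna_de["status"] != "ns").sum()),
        "n_dm_genes": int((meth_de["status"] != "ns").sum()),
        "n_recurrent_cna": int(len(recurrent)),
        "candidate_set_sizes": overlap["set_sizes"],
        "venn_regions": overlap["regions"],
        "n_functional_pairs": int(len(functional)),
        "deg_network": {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges()},
        "subnetworks": subnet_sizes,
        "hubs": {m: sorted(t.index) for m, t in hubs_by_network.items()},
        "cross_network_key_genes": sorted(cross.index),
        "key_genes": sorted(hub_table.index),
        "n_enriched_terms": int(len(enriched)),
    }
    save_json(summary, "summary.json")
    thresholds = {
        k: getattr(config, k)
        for k in ("fc_min", "p_max", "min_algorithms", "r_max", "pair_p_max",
                  "cna_r_min", "cna_p_max", "score_min", "hub_k", "recur_q_max", "enrich_p_max")
    }
    thresholds["call_thresholds"] = dataclasses.asdict(config.call_thresholds)
    manifest = {
        "seed": config.seed,
        "thresholds": thresholds,
        "simulate": dataclasses.asdict(sim) if config.simulate is not None else None,
        "inputs": {k: str(v) for k, v in sorted(config.inputs.items())},
        "summary": summary,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return RunResult(
        cohort=cohort, gene_de=gene_de, mirna_de=mirna_de, meth_de=meth_de,
        recurrent=recurrent, candidate_sets=sets, overlap=overlap, functional=functional,
        centrality_tables=centrality_tables, hubs_by_network=hubs_by_network,
        cross_degree=cross, hub_table=hub_table, enrichment=enriched, manifest=manifest,
    )
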