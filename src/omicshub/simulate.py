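"""Synthetic paired tumor/normal multi-omics cohorts with planted signal.

The generator emulates the shape of a paired-cohort integration study:
every patient contributes a tumor sample; a subset also contributes a
matched normal. Three feature layers are produced — gene expression,
miRNA expression (both log-normal around log2-scale latent means, so the
values are non-negative like RPKM/RPM abundances) and methylation beta
values (a logistic squash of a Gaussian latent, so values stay in
(0, 1)) — plus a segmented copy-number table for the tumor samples, a
BED-like gene coordinate table, a miRNA->target prediction map with
algorithm-support counts, a scored PPI edge list, and ground-truth
labels for everything planted.

Planted structure, all driven by one seed:

* differentially expressed genes and miRNAs (additive log2 effect in the
  tumor samples, half up / half down);
* miRNA repression pairs — an anti-correlated latent factor is shared by
  the miRNA (positively) and its target gene (negatively) across tumor
  samples, on top of opposite differential directions;
* methylation silencing/activation — planted genes move between a low
  (~0.15) and high (~0.6) beta level opposite to their expression shift,
  a genuine >=4-fold change of beta;
* copy-number dosage — planted genes sit in their own focal segments
  whose per-tumor-sample log2 ratio (around +1.2 for amplification,
  -1.8 for homozygous deletion) feeds back, mean-centered, into the
  gene's expression latent, giving a positive expression-dosage
  correlation;
* a PPI graph in which designated key genes are wired as hubs (>= 15
  differentially expressed neighbors each) on top of an Erdős–Rényi
  background. A small "hub tail" of high-degree non-candidate genes with
  spread-out degrees is added so that the degree distribution, like a
  real protein network's, has many distinct values in its upper tail and
  top-k rank cutoffs are meaningful.

One gene (when all three planted counts allow) is planted in all three
regulatory layers — down-regulated, hypermethylated, homozygously
deleted and targeted by an up-regulated miRNA — so the triple
intersection of candidate sets is non-empty by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneTable, OmicsMatrix, SegmentTable, TargetMap, TruthLabels
from . import io as ohio

MECHANISMS = ("mirna", "meth", "cna")

# focal copy-ratio doses (log2) and their per-sample spread
AMP_DOSE, DEL_DOSE, DOSE_SD = 1.2, -1.8, 0.4
# shared miRNA-target latent factor spread (log2 units, tumor samples)
REPRESSION_SD = 0.4
# beta levels between which planted methylation genes move
BETA_LOW, BETA_HIGH = 0.15, 0.6
KEY_NEIGHBORS = 30      # DE neighbors wired to each planted key gene
HUB_TAIL_SIZE = 16      # non-candidate high-degree background genes
HUB_TAIL_MIN_DEGREE = 15


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for one synthetic cohort."""

    n_patients: int = 60
    n_paired: int = 30
    n_genes: int = 2000
    n_mirnas: int = 300
    n_methylation_sites: int = 3000
    frac_de_genes: float = 0.15
    planted_mirna_pairs: int = 25
    planted_meth_genes: int = 25
    planted_cna_genes: int = 25
    effect_log2fc: float = 2.0
    noise_sd: float = 0.3
    ppi_edge_prob: float = 0.02
    n_key_genes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_paired", "n_genes", "n_mirnas", "n_methylation_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("planted_mirna_pairs", "planted_meth_genes", "planted_cna_genes", "n_key_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.frac_de_genes <= 1.0:
            raise ValueError("frac_de_genes must lie in [0, 1]")
        if not 0.0 <= self.ppi_edge_prob <= 1.0:
            raise ValueError("ppi_edge_prob must lie in [0, 1]")
        if self.n_paired > self.n_patients:
            raise ValueError("n_paired cannot exceed n_patients")
        if self.noise_sd < 0 or self.effect_log2fc < 0:
            raise ValueError("noise_sd and effect_log2fc must be non-negative")
        n_de = round(self.frac_de_genes * self.n_genes)
        n_planted = self.planted_mirna_pairs + self.planted_meth_genes + self.planted_cna_genes
        if n_planted > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if n_planted > 0 and n_planted - 2 > n_de:
            raise ValueError(
                f"planted gene counts ({n_planted}) exceed the DE gene pool "
                f"({n_de}); raise frac_de_genes or n_genes"
            )
        if self.planted_mirna_pairs > self.n_mirnas:
            raise ValueError("planted_mirna_pairs exceeds n_mirnas")


@dataclass
class Cohort:
    """Everything one synthetic study produces, plus its ground truth."""

    expression: OmicsMatrix
    mirna: OmicsMatrix
    methylation: OmicsMatrix          # site-level beta values
    site_to_gene: pd.DataFrame
    segments: SegmentTable
    genes: GeneTable
    targets: TargetMap
    ppi_edges: pd.DataFrame
    truth: TruthLabels
    config: CohortConfig = field(repr=False, default=None)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate one cohort; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    c = config

    genes = [f"G{i:05d}" for i in range(c.n_genes)]
    mirnas = [f"MIR{i:04d}" for i in range(c.n_mirnas)]
    sites = [f"CG{i:06d}" for i in range(c.n_methylation_sites)]
    patients = [f"P{i:03d}" for i in range(c.n_patients)]
    tumor_samples = [f"{p}-T" for p in patients]
    normal_samples = [f"{p}-N" for p in patients[: c.n_paired]]
    samples = tumor_samples + normal_samples
    meta = pd.DataFrame(
        {
            "patient_id": patients + patients[: c.n_paired],
            "tissue": ["tumor"] * len(tumor_samples) + ["normal"] * len(normal_samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    is_tumor = np.array([t == "tumor" for t in meta["tissue"]])

    # --- differential truth -------------------------------------------------
    n_de = round(c.frac_de_genes * c.n_genes)
    de_gene_idx = rng.choice(c.n_genes, size=n_de, replace=False)
    gene_sign = np.zeros(c.n_genes)
    gene_sign[de_gene_idx[: n_de // 2]] = 1.0
    gene_sign[de_gene_idx[n_de // 2:]] = -1.0

    n_de_mir = round(c.frac_de_genes * c.n_mirnas)
    de_mir_idx = rng.choice(c.n_mirnas, size=n_de_mir, replace=False)
    mir_sign = np.zeros(c.n_mirnas)
    mir_sign[de_mir_idx[: n_de_mir // 2]] = 1.0
    mir_sign[de_mir_idx[n_de_mir // 2:]] = -1.0

    de_up = {genes[i] for i in np.where(gene_sign > 0)[0]}
    de_down = {genes[i] for i in np.where(gene_sign < 0)[0]}

    # --- planted mechanism assignments -------------------------------------
    de_pool = [genes[i] for i in sorted(de_gene_idx)]
    rng.shuffle(de_pool)
    triple_gene = None
    counts = (c.planted_mirna_pairs, c.planted_meth_genes, c.planted_cna_genes)
    if all(k >= 1 for k in counts):
        # the triple-layer gene must be down-regulated (hyper + deletion story)
        downs = [g for g in de_pool if g in de_down]
        if downs:
            triple_gene = downs[0]
            de_pool.remove(triple_gene)

    pools: dict[str, list] = {}
    cursor = 0
    for mech, k in zip(MECHANISMS, counts):
        own = k - (1 if triple_gene is not None and k >= 1 else 0)
        pools[mech] = ([triple_gene] if triple_gene is not None and k >= 1 else []) + de_pool[cursor: cursor + own]
        cursor += own

    # miRNA partners: a distinct DE miRNA of the opposite direction per gene
    planted_pairs: list[tuple[str, str, str]] = []
    ups = [mirnas[i] for i in sorted(np.where(mir_sign > 0)[0])]
    downs_m = [mirnas[i] for i in sorted(np.where(mir_sign < 0)[0])]
    need_up = sum(1 for g in pools["mirna"] if g in de_down)
    need_down = len(pools["mirna"]) - need_up
    if need_up > len(ups) or need_down > len(downs_m):
        raise ValueError("not enough differentially expressed miRNAs for the planted pairs")
    ups_iter, downs_iter = iter(ups), iter(downs_m)
    for g in pools["mirna"]:
        m = next(ups_iter) if g in de_down else next(downs_iter)
        planted_pairs.append((m, g, "repression"))

    planted_meth = [(g, "hyper" if g in de_down else "hypo") for g in pools["meth"]]
    planted_cna = [(g, "del" if g in de_down else "amp") for g in pools["cna"]]

    # key genes: one planted gene per mechanism, round-robin, triple excluded
    key_genes: dict[str, str] = {}
    for i in range(c.n_key_genes):
        mech = MECHANISMS[i % 3]
        avail = [g for g in pools[mech] if g != triple_gene and g not in key_genes]
        if avail:
            key_genes[avail[0]] = mech

    # --- expression layers ---------------------------------------------------
    gene_base = rng.uniform(3.0, 8.0, size=c.n_genes)
    latent = gene_base[:, None] + rng.normal(0.0, c.noise_sd, size=(c.n_genes, len(samples)))
    latent[:, is_tumor] += (gene_sign * c.effect_log2fc)[:, None]

    mir_base = rng.uniform(3.0, 8.0, size=c.n_mirnas)
    mir_latent = mir_base[:, None] + rng.normal(0.0, c.noise_sd, size=(c.n_mirnas, len(samples)))
    mir_latent[:, is_tumor] += (mir_sign * c.effect_log2fc)[:, None]

    gene_index = {g: i for i, g in enumerate(genes)}
    mir_index = {m: i for i, m in enumerate(mirnas)}
    n_tumor = int(is_tumor.sum())

    for m, g, _ in planted_pairs:  # shared repression factor, tumor side
        d = rng.normal(0.0, REPRESSION_SD, size=n_tumor)
        d -= d.mean()
        mir_latent[mir_index[m], is_tumor] += d
        latent[gene_index[g], is_tumor] -= d

    dose: dict[str, np.ndarray] = {}  # gene -> per-tumor-sample log2 copy ratio
    for g, state in planted_cna:
        mu = AMP_DOSE if state == "amp" else DEL_DOSE
        cvec = rng.normal(mu, DOSE_SD, size=n_tumor)
        dose[g] = cvec
        latent[gene_index[g], is_tumor] += cvec - cvec.mean()

    expr = OmicsMatrix(
        pd.DataFrame(np.power(2.0, latent), index=pd.Index(genes, name="gene_id"), columns=samples),
        meta,
    )
    mirna_mat = OmicsMatrix(
        pd.DataFrame(np.power(2.0, mir_latent), index=pd.Index(mirnas, name="mirna_id"), columns=samples),
        meta,
    )

    # --- methylation ---------------------------------------------------------
    site_gene = [genes[i % c.n_genes] for i in range(c.n_methylation_sites)]
    site_to_gene = pd.DataFrame({"site_id": sites, "gene_id": site_gene})
    base_beta = rng.uniform(0.2, 0.8, size=c.n_genes)
    meth_latent_normal = np.array([_logit(b) for b in base_beta])
    meth_latent_tumor = meth_latent_normal.copy()
    for g, direction in planted_meth:
        i = gene_index[g]
        lo, hi = _logit(BETA_LOW), _logit(BETA_HIGH)
        if direction == "hyper":
            meth_latent_normal[i], meth_latent_tumor[i] = lo, hi
        else:
            meth_latent_normal[i], meth_latent_tumor[i] = hi, lo
    site_offset = rng.normal(0.0, 0.2, size=c.n_methylation_sites)
    gene_rows = np.array([gene_index[g] for g in site_gene])
    site_latent = np.where(
        is_tumor[None, :], meth_latent_tumor[gene_rows][:, None], meth_latent_normal[gene_rows][:, None]
    )
    site_latent = site_latent + site_offset[:, None] + rng.normal(0.0, c.noise_sd, size=(c.n_methylation_sites, len(samples)))
    meth = OmicsMatrix(
        pd.DataFrame(_sigmoid(site_latent), index=pd.Index(sites, name="site_id"), columns=samples),
        meta,
    )

    # --- genome layout and segments -----------------------------------------
    n_chrom = 10
    per_chrom = -(-c.n_genes // n_chrom)
    gene_span, gene_gap = 5_000, 10_000
    grows = []
    for i, g in enumerate(genes):
        chrom = str(i // per_chrom + 1)
        start = (i % per_chrom) * gene_gap + 1_000
        grows.append((chrom, start, start + gene_span, g))
    gene_table = GeneTable(pd.DataFrame(grows, columns=["chrom", "start", "end", "gene_id"]))

    chrom_len = per_chrom * gene_gap + 10_000
    planted_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    gdf = gene_table.df.set_index("gene_id")
    for g, _state in planted_cna:
        row = gdf.loc[g]
        planted_by_chrom.setdefault(row["chrom"], []).append((int(row["start"]), int(row["end"]), g))
    seg_rows = []
    for si, sample in enumerate(tumor_samples):
        for ci in range(n_chrom):
            chrom = str(ci + 1)
            cuts = sorted(planted_by_chrom.get(chrom, []))
            pos = 0
            for gstart, gend, g in cuts:
                if gstart > pos:
                    seg_rows.append((sample, chrom, pos + 1, gstart, float(rng.normal(0.0, 0.05))))
                seg_rows.append((sample, chrom, gstart + 1, gend, float(dose[g][si])))
                pos = gend
            if pos < chrom_len:
                seg_rows.append((sample, chrom, pos + 1, chrom_len, float(rng.normal(0.0, 0.05))))
    segments = SegmentTable(
        pd.DataFrame(seg_rows, columns=["sample_id", "chromosome", "start", "end", "seg_mean"])
    )

    # decoy hub-tail genes are fixed before the target map so they can be
    # excluded from random target pairs (a decoy must stay non-candidate)
    de_genes_sorted = sorted(de_up | de_down)
    planted_any = set(pools["mirna"]) | set(pools["meth"]) | set(pools["cna"])
    decoy_pool = [g for g in de_genes_sorted if g not in planted_any]
    decoys = decoy_pool[:HUB_TAIL_SIZE]

    # --- miRNA target map -----------------------------------------------------
    trows = [(m, g, int(rng.integers(3, 6))) for m, g, _ in planted_pairs]
    planted_set = {(m, g) for m, g, _ in planted_pairs}
    protected = set(key_genes) | {g for g, _ in planted_cna} | {g for g, _ in planted_meth} | set(decoys)
    bg_gene_pool = [g for g in genes if g not in protected]
    n_background = 3 * c.n_mirnas
    for _ in range(n_background):
        m = mirnas[int(rng.integers(0, c.n_mirnas))]
        g = bg_gene_pool[int(rng.integers(0, len(bg_gene_pool)))]
        if (m, g) in planted_set:
            continue
        planted_set.add((m, g))
        trows.append((m, g, int(rng.integers(1, 6))))
    targets = TargetMap(pd.DataFrame(trows, columns=["mirna_id", "gene_id", "n_algorithms"]))

    # --- PPI edge list ---------------------------------------------------------
    non_de = [g for g in genes if gene_sign[gene_index[g]] == 0]
    extra = list(rng.choice(non_de, size=min(100, len(non_de)), replace=False)) if non_de else []
    pool = de_genes_sorted + sorted(extra)
    edge_scores: dict[tuple[str, str], float] = {}

    def add_edge(a: str, b: str, score: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        edge_scores.setdefault(key, round(float(score), 3))

    npool = len(pool)
    if npool > 1 and c.ppi_edge_prob > 0:
        upper = np.triu_indices(npool, k=1)
        mask = rng.random(len(upper[0])) < c.ppi_edge_prob
        scores = rng.uniform(0.15, 1.0, size=int(mask.sum()))
        for (ia, ib), sc in zip(zip(upper[0][mask], upper[1][mask]), scores):
            add_edge(pool[ia], pool[ib], sc)

    for j, dgene in enumerate(decoys):
        targets_j = [g for g in de_genes_sorted if g != dgene]
        picks = rng.choice(len(targets_j), size=min(HUB_TAIL_MIN_DEGREE + j, len(targets_j)), replace=False)
        for pidx in picks:
            add_edge(dgene, targets_j[pidx], rng.uniform(0.4, 1.0))
    for kgene in key_genes:
        neighbors = [g for g in de_genes_sorted if g != kgene]
        picks = rng.choice(len(neighbors), size=min(KEY_NEIGHBORS, len(neighbors)), replace=False)
        for pidx in picks:
            add_edge(kgene, neighbors[pidx], rng.uniform(0.4, 1.0))
        for dgene in decoys:
            add_edge(kgene, dgene, rng.uniform(0.4, 1.0))

    ppi_edges = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edge_scores.items())],
        columns=["gene_a", "gene_b", "score"],
    )

    truth = TruthLabels(
        de_genes_up=de_up,
        de_genes_down=de_down,
        de_mirnas_up={mirnas[i] for i in np.where(mir_sign > 0)[0]},
        de_mirnas_down={mirnas[i] for i in np.where(mir_sign < 0)[0]},
        planted_pairs=planted_pairs,
        planted_meth=planted_meth,
        planted_cna=planted_cna,
        key_genes=set(key_genes),
        key_gene_mechanism=dict(key_genes),
    )
    return Cohort(expr, mirna_mat, meth, site_to_gene, segments, gene_table, targets, ppi_edges, truth, c)


FIXTURE_FILES = (
    "expression.tsv",
    "mirna.tsv",
    "methylation_sites.tsv",
    "sample_meta.tsv",
    "site_to_gene.tsv",
    "segments.seg",
    "genes.bed",
    "targets.tsv",
    "ppi_edges.tsv",
    "truth.json",
)


def write_fixtures(cohort: Cohort, out_dir) -> list[str]:
    """Write the cohort as plain-text files; returns the file manifest.

    The files round-trip through :mod:`omicshub.io` readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ohio.write_matrix(cohort.expression, out / "expression.tsv")
    ohio.write_matrix(cohort.mirna, out / "mirna.tsv")
    ohio.write_matrix(cohort.methylation, out / "methylation_sites.tsv")
    ohio.write_sample_meta(cohort.expression.sample_meta, out / "sample_meta.tsv")
    ohio.write_site_map(cohort.site_to_gene, out / "site_to_gene.tsv")
    ohio.write_seg(cohort.segments, out / "segments.seg")
    ohio.write_gene_table(cohort.genes, out / "genes.bed")
    ohio.write_target_map(cohort.targets, out / "targets.tsv")
    ohio.write_edge_list(cohort.ppi_edges, out / "ppi_edges.tsv")
    ohio.write_truth(cohort.truth, out / "truth.json")
    return [str(out / name) for name in FIXTURE_FILES]
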