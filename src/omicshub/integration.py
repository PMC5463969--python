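"""Bimodal filtering: intersect DEGs with direction-appropriate regulation.

A differentially expressed gene becomes a *candidate* when an upstream
regulatory layer changed in the direction that explains its expression
shift:

* miRNA layer — an up-regulated miRNA predicted (by at least three
  algorithms) to target a down-regulated gene, or vice versa;
* methylation layer — hypomethylation with over-expression, or
  hypermethylation with under-expression;
* copy-number layer — recurrent amplification with over-expression, or
  recurrent homozygous deletion with under-expression, additionally
  gated on a positive expression-dosage Pearson correlation (r > 0.5,
  P < 0.05 by default).

miRNA-gene pairs can further be restricted to *functional pairs* with
significantly negative expression correlation (r < -0.1, P < 0.05); the
unrestricted candidate set and the correlation-restricted subset are both
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix, TargetMap, log2_transform
from .differential import status_sets

logger = logging.getLogger(__name__)


@dataclass
class CandidateGeneSets:
    """The three regulator-controlled DEG subsets and their annotations."""

    mirna_set: set = field(default_factory=set)
    meth_set: set = field(default_factory=set)
    cna_set: set = field(default_factory=set)
    mirna_annotations: pd.DataFrame | None = None  # gene_id, direction, mirnas, n_mirnas
    meth_annotations: pd.DataFrame | None = None   # gene_id, direction, methylation
    cna_annotations: pd.DataFrame | None = None    # gene_id, direction, cna, r, p

    def by_mechanism(self) -> dict[str, set]:
        return {"mirna": self.mirna_set, "meth": self.meth_set, "cna": self.cna_set}


def filter_targets(targets: TargetMap, min_algorithms: int = 3) -> TargetMap:
    """Keep miRNA-target pairs supported by >= min_algorithms predictors."""
    kept = targets.df[targets.df["n_algorithms"] >= min_algorithms]
    return TargetMap(kept.reset_index(drop=True))


def mirna_bimodal_filter(
    gene_de: pd.DataFrame, mirna_de: pd.DataFrame, targets: TargetMap
) -> tuple[pd.DataFrame, set]:
    """Anti-directional miRNA-target pairs among DE features.

    Keeps target pairs where the miRNA is up and the gene down, or the
    miRNA down and the gene up. Returns (kept pair table with columns
    mirna_id/gene_id/mirna_status/gene_status, gene candidate set).
    """
    g_up, g_down = status_sets(gene_de)
    m_up, m_down = status_sets(mirna_de)
    df = targets.df
    keep = (
        (df["mirna_id"].isin(m_up) & df["gene_id"].isin(g_down))
        | (df["mirna_id"].isin(m_down) & df["gene_id"].isin(g_up))
    )
    pairs = df.loc[keep, ["mirna_id", "gene_id"]].copy()
    pairs["mirna_status"] = np.where(pairs["mirna_id"].isin(m_up), "up", "down")
    pairs["gene_status"] = np.where(pairs["gene_id"].isin(g_up), "up", "down")
    return pairs.reset_index(drop=True), set(pairs["gene_id"])


def correlate(
    pairs: pd.DataFrame,
    matrix_a: OmicsMatrix,
    matrix_b: OmicsMatrix,
    tissue: str = "tumor",
    log_transform: bool = True,
    pseudocount: float = 1.0,
    id_cols: tuple[str, str] = ("mirna_id", "gene_id"),
) -> pd.DataFrame:
    """Pearson correlation per pair over samples shared by both matrices.

    ``pairs`` holds feature ids of ``matrix_a`` in ``id_cols[0]`` and of
    ``matrix_b`` in ``id_cols[1]``. Correlations are computed over the
    common samples of the requested tissue (tumor by default — dosage and
    repression relationships are properties of the tumors). P values are
    two-sided from t = r*sqrt((n-2)/(1-r^2)) on n-2 df. Pairs with zero
    variance in either vector get r = NaN and are logged; callers exclude
    them downstream.
    """
    common = [s for s in matrix_a.samples_of(tissue) if s in set(matrix_b.samples_of(tissue))]
    if len(common) < 3:
        raise ValueError(f"need >=3 common {tissue} samples, got {len(common)}")
    va = matrix_a.values[common]
    vb = matrix_b.values[common]
    if log_transform:
        va = log2_transform(va, pseudocount)
        vb = log2_transform(vb, pseudocount)
    n = len(common)
    records = []
    for a_id, b_id in pairs[list(id_cols)].itertuples(index=False):
        x = va.loc[a_id].to_numpy(dtype=float)
        y = vb.loc[b_id].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("undefined correlation (zero variance): %s ~ %s", a_id, b_id)
            records.append((a_id, b_id, np.nan, np.nan, n))
            continue
        r, p = stats.pearsonr(x, y)
        records.append((a_id, b_id, float(r), float(p), n))
    return pd.DataFrame(records, columns=["id_a", "id_b", "r", "p", "n"])


def functional_pairs(records: pd.DataFrame, r_max: float = -0.1, p_max: float = 0.05) -> pd.DataFrame:
    """Pairs with significantly negative correlation: r < r_max and P < p_max."""
    keep = (records["r"] < r_max) & (records["p"] < p_max)
    return records.loc[keep.fillna(False)].reset_index(drop=True)


def methylation_bimodal_filter(gene_de: pd.DataFrame, meth_de: pd.DataFrame) -> tuple[pd.DataFrame, set]:
    """Genes whose expression and promoter methylation moved oppositely.

    ``meth_de`` is the classified differential table of the gene-level
    methylation matrix (status up = hypermethylated). Returns (annotation
    table with columns gene_id/direction/methylation, gene set):
    over-expressed & hypomethylated -> ``hypo``; under-expressed &
    hypermethylated -> ``hyper``.
    """
    g_up, g_down = status_sets(gene_de)
    m_up, m_down = status_sets(meth_de)
    hypo = sorted(g_up & m_down)
    hyper = sorted(g_down & m_up)
    ann = pd.DataFrame(
        {
            "gene_id": hypo + hyper,
            "direction": ["up"] * len(hypo) + ["down"] * len(hyper),
            "methylation": ["hypo"] * len(hypo) + ["hyper"] * len(hyper),
        }
    )
    return ann, set(ann["gene_id"])


def cna_bimodal_filter(
    gene_de: pd.DataFrame,
    amplified: set,
    deleted: set,
    expr: OmicsMatrix,
    ratios: pd.DataFrame,
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> tuple[pd.DataFrame, set]:
    """DEGs with concordant recurrent copy-number change and dosage effect.

    Over-expressed & recurrently amplified, or under-expressed &
    recurrently (homozygously) deleted genes whose log2 expression
    correlates with the copy ratio across tumor samples at r > r_min and
    P < p_max. Returns (annotation table gene_id/direction/cna/r/p, set).
    """
    g_up, g_down = status_sets(gene_de)
    concordant = [(g, "up", "amp") for g in sorted(g_up & amplified)]
    concordant += [(g, "down", "del") for g in sorted(g_down & deleted)]
    tumor = [s for s in expr.samples_of("tumor") if s in set(ratios.columns)]
    if len(tumor) < 3:
        raise ValueError("need >=3 tumor samples shared by expression and copy ratios")
    log_expr = log2_transform(expr.values[tumor], 1.0)
    rows = []
    for gene, direction, state in concordant:
        if gene not in ratios.index or gene not in log_expr.index:
            continue
        x = log_expr.loc[gene].to_numpy(dtype=float)
        y = ratios.loc[gene, tumor].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            logger.warning("undefined dosage correlation for %s", gene)
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        if r > r_min and p < p_max:
            rows.append((gene, direction, state, float(r), float(p)))
    ann = pd.DataFrame(rows, columns=["gene_id", "direction", "cna", "r", "p"])
    return ann, set(ann["gene_id"])


def overlap_analysis(sets: CandidateGeneSets) -> dict:
    """Venn decomposition of the three candidate sets.

    Returns the seven exclusive region counts, the genes in at least two
    sets, and the triple intersection.
    """
    a, b, c = sets.mirna_set, sets.meth_set, sets.cna_set
    triple = a & b & c
    regions = {
        "mirna_only": len(a - b - c),
        "meth_only": len(b - a - c),
        "cna_only": len(c - a - b),
        "mirna_meth": len((a & b) - c),
        "mirna_cna": len((a & c) - b),
        "meth_cna": len((b & c) - a),
        "triple": len(triple),
    }
    in_two_or_more = (a & b) | (a & c) | (b & c)
    return {
        "regions": regions,
        "genes_in_two_or_more": sorted(in_two_or_more),
        "triple_intersection": sorted(triple),
        "set_sizes": {"mirna": len(a), "meth": len(b), "cna": len(c)},
    }


def build_candidate_sets(
    mirna_pairs: pd.DataFrame,
    mirna_set: set,
    gene_de: pd.DataFrame,
    meth_ann: pd.DataFrame,
    meth_set: set,
    cna_ann: pd.DataFrame,
    cna_set: set,
) -> CandidateGeneSets:
    """Assemble CandidateGeneSets with per-gene annotations.

    A gene admitted by several miRNAs is listed once with all its
    supporting miRNAs and their count.
    """
    if len(mirna_pairs):
        grouped = (
            mirna_pairs.groupby("gene_id")
            .agg(direction=("gene_status", "first"), mirnas=("mirna_id", lambda s: ",".join(sorted(s))), n_mirnas=("mirna_id", "nunique"))
            .reset_index()
        )
    else:
        grouped = pd.DataFrame(columns=["gene_id", "direction", "mirnas", "n_mirnas"])
    return CandidateGeneSets(
        mirna_set=set(mirna_set),
        meth_set=set(meth_set),
        cna_set=set(cna_set),
        mirna_annotations=grouped,
        meth_annotations=meth_ann,
        cna_annotations=cna_ann,
    )
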