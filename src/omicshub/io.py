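"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated. Matrices carry the feature id in the first
column and sample ids in the header; sample metadata, SEG segments,
BED-like gene coordinates, miRNA target maps and scored edge lists follow
the column layouts documented on the corresponding containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import GeneTable, OmicsMatrix, SegmentTable, TargetMap, TruthLabels


def read_matrix(matrix_path, meta_path) -> OmicsMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return OmicsMatrix(values, meta)


def write_matrix(matrix: OmicsMatrix, matrix_path, meta_path=None) -> None:
    df = matrix.values.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(matrix_path, sep="\t")
    if meta_path is not None:
        write_sample_meta(matrix.sample_meta, meta_path)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_seg(path) -> SegmentTable:
    df = pd.read_csv(path, sep="\t")
    # tolerate the common SEG header variants (Sample/Chromosome/Start/End/Segment_Mean)
    rename = {}
    for col in df.columns:
        key = col.lower().strip().replace("_", "").replace(".", "")
        rename[col] = {
            "sample": "sample_id", "sampleid": "sample_id", "id": "sample_id",
            "chromosome": "chromosome", "chrom": "chromosome", "chr": "chromosome",
            "start": "start", "locstart": "start",
            "end": "end", "locend": "end", "stop": "end",
            "segmean": "seg_mean", "segmentmean": "seg_mean", "mean": "seg_mean",
            "nummark": "num_mark", "numprobes": "num_mark", "markers": "num_mark",
        }.get(key, col)
    df = df.rename(columns=rename)
    df["chromosome"] = df["chromosome"].astype(str)
    return SegmentTable(df)


def write_seg(segments: SegmentTable, path) -> None:
    segments.df.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> GeneTable:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:4]) != ["chrom", "start", "end", "gene_id"]:
        df.columns = ["chrom", "start", "end", "gene_id"] + list(df.columns[4:])
    df["chrom"] = df["chrom"].astype(str)
    return GeneTable(df)


def write_gene_table(genes: GeneTable, path) -> None:
    genes.df.to_csv(path, sep="\t", index=False)


def read_target_map(path) -> TargetMap:
    return TargetMap(pd.read_csv(path, sep="\t"))


def write_target_map(targets: TargetMap, path) -> None:
    targets.df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    """Scored PPI edge list: columns gene_a, gene_b, score."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["gene_a", "gene_b", "score"]:
        df.columns = ["gene_a", "gene_b", "score"] + list(df.columns[3:])
    return df


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_site_map(path) -> pd.DataFrame:
    """Methylation site -> gene mapping: columns site_id, gene_id."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["site_id", "gene_id"]:
        df.columns = ["site_id", "gene_id"] + list(df.columns[2:])
    return df


def write_site_map(site_map: pd.DataFrame, path) -> None:
    site_map.to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthLabels:
    with open(path) as fh:
        return TruthLabels.from_dict(json.load(fh))


def write_truth(truth: TruthLabels, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n")
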