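"""Shared in-memory containers for the pipeline.

The common carrier for expression, miRNA and methylation data is
:class:`OmicsMatrix`: a feature x sample numeric matrix plus per-sample
metadata (patient label and tissue). Tumor/normal pairing is expressed
through shared ``patient_id`` values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("tumor", "normal")


@dataclass
class OmicsMatrix:
    """Feature x sample numeric matrix with tumor/normal pairing metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids. Expression
        values are non-negative; methylation beta values lie in (0, 1).
    sample_meta
        DataFrame indexed by sample id with columns ``patient_id`` and
        ``tissue`` (``tumor`` or ``normal``). Every column of ``values``
        must appear in the index.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        bad = set(self.sample_meta["tissue"]) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, tissue: str) -> list[str]:
        """Sample ids of one tissue, in matrix column order."""
        keep = self.sample_meta.loc[self.sample_meta["tissue"] == tissue].index
        return [s for s in self.values.columns if s in set(keep)]

    def paired_samples(self) -> pd.DataFrame:
        """Tumor/normal sample pairs sharing a patient id.

        Returns a DataFrame with columns ``patient_id``, ``tumor``,
        ``normal`` — one row per patient having exactly one sample of each
        tissue in this matrix. Unpaired samples are dropped (they play no
        role in paired differential analysis).
        """
        meta = self.sample_meta.loc[self.values.columns]
        rows = []
        for patient, grp in meta.groupby("patient_id", sort=True):
            tum = grp.index[grp["tissue"] == "tumor"]
            nor = grp.index[grp["tissue"] == "normal"]
            if len(tum) == 1 and len(nor) == 1:
                rows.append((patient, tum[0], nor[0]))
        return pd.DataFrame(rows, columns=["patient_id", "tumor", "normal"])

    def subset_features(self, ids) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(ids)], self.sample_meta)


@dataclass
class SegmentTable:
    """Segmented copy-number data (SEG): one row per segment.

    Columns: ``sample_id``, ``chromosome``, ``start``, ``end`` (1-based
    inclusive, as in the SEG format), ``seg_mean`` (log2 copy ratio).
    """

    df: pd.DataFrame
    REQUIRED = ("sample_id", "chromosome", "start", "end", "seg_mean")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"segment table missing columns {sorted(missing)}")
        if (self.df["start"] > self.df["end"]).any():
            raise ValueError("segment with start > end")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())


@dataclass
class GeneTable:
    """BED-like gene coordinates: ``chrom``, ``start``, ``end``, ``gene_id``.

    Coordinates are 0-based half-open, the BED convention.
    """

    df: pd.DataFrame
    REQUIRED = ("chrom", "start", "end", "gene_id")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"gene table missing columns {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in gene table")


@dataclass
class TargetMap:
    """miRNA -> target-gene predictions with per-pair algorithm support.

    ``df`` columns: ``mirna_id``, ``gene_id``, ``n_algorithms`` (1..5, the
    number of prediction algorithms supporting the pair).
    """

    df: pd.DataFrame
    REQUIRED = ("mirna_id", "gene_id", "n_algorithms")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"target map missing columns {sorted(missing)}")
        if (self.df["n_algorithms"] < 1).any():
            raise ValueError("n_algorithms must be >= 1")
        if self.df.duplicated(["mirna_id", "gene_id"]).any():
            raise ValueError("duplicate (mirna, gene) pairs in target map")


@dataclass
class TruthLabels:
    """Ground truth for a synthetic cohort (planted signal labels)."""

    de_genes_up: set = field(default_factory=set)
    de_genes_down: set = field(default_factory=set)
    de_mirnas_up: set = field(default_factory=set)
    de_mirnas_down: set = field(default_factory=set)
    planted_pairs: list = field(default_factory=list)   # (mirna, gene, "repression")
    planted_meth: list = field(default_factory=list)    # (gene, "hyper"|"hypo")
    planted_cna: list = field(default_factory=list)     # (gene, "amp"|"del")
    key_genes: set = field(default_factory=set)
    key_gene_mechanism: dict = field(default_factory=dict)  # gene -> mechanism

    def to_dict(self) -> dict:
        return {
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "de_mirnas_up": sorted(self.de_mirnas_up),
            "de_mirnas_down": sorted(self.de_mirnas_down),
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "planted_meth": [list(p) for p in self.planted_meth],
            "planted_cna": [list(p) for p in self.planted_cna],
            "key_genes": sorted(self.key_genes),
            "key_gene_mechanism": dict(sorted(self.key_gene_mechanism.items())),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthLabels":
        return cls(
            de_genes_up=set(d["de_genes_up"]),
            de_genes_down=set(d["de_genes_down"]),
            de_mirnas_up=set(d["de_mirnas_up"]),
            de_mirnas_down=set(d["de_mirnas_down"]),
            planted_pairs=[tuple(p) for p in d["planted_pairs"]],
            planted_meth=[tuple(p) for p in d["planted_meth"]],
            planted_cna=[tuple(p) for p in d["planted_cna"]],
            key_genes=set(d["key_genes"]),
            key_gene_mechanism=dict(d.get("key_gene_mechanism", {})),
        )


def log2_transform(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount); requires x + pseudocount > 0 everywhere."""
    shifted = values + pseudocount
    if (shifted <= 0).any().any():
        raise ValueError("non-positive values after pseudocount; cannot log-transform")
    return np.log2(shifted)
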