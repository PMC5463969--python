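"""Gene-level copy-number calling from segmented data.

Segments (log2 copy ratios from upstream circular-binary-segmentation
output) are mapped to genes by interval overlap; each gene takes the
ratio of the single segment covering the largest share of it. Ratios are
discretised into the five standard states — homozygous deletion,
heterozygous deletion, diploid, gain, amplification — and only the two
extreme states (amplification, homozygous deletion) count as significant
changes in a sample. Recurrently altered genes are found with a per-gene
binomial test of the per-sample alteration frequency against the
cohort-wide background rate of that state; this frequency test is a
deliberately simple stand-in for a full positional recurrence model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneTable, SegmentTable
from .differential import bh_adjust

logger = logging.getLogger(__name__)

STATES = ("homdel", "hetdel", "diploid", "gain", "amp")


@dataclass(frozen=True)
class CallThresholds:
    """Log2-ratio cutoffs for the five-state call.

    Defaults (-1.3 / -0.3 / 0.3 / 0.9) follow common SNP6 practice:
    homdel if ratio <= t_homdel, hetdel if <= t_hetdel, gain if >= t_gain
    and below t_amp, amp if >= t_amp, diploid otherwise. The extreme
    boundaries are inclusive on the extreme side.
    """

    t_homdel: float = -1.3
    t_hetdel: float = -0.3
    t_gain: float = 0.3
    t_amp: float = 0.9

    def __post_init__(self) -> None:
        if not (self.t_homdel < self.t_hetdel < self.t_gain < self.t_amp):
            raise ValueError("thresholds must satisfy t_homdel < t_hetdel < t_gain < t_amp")


def map_segments_to_genes(segments: SegmentTable, genes: GeneTable) -> pd.DataFrame:
    """Gene x sample matrix of log2 ratios by largest-overlap assignment.

    SEG coordinates are 1-based inclusive and gene coordinates 0-based
    half-open; both are converted to half-open internally. A gene
    overlapping several segments of one sample takes the seg_mean of the
    segment with the largest overlap length (ties broken by earlier
    segment start). Genes with no overlapping segment are NaN for that
    sample; chromosomes absent from a sample's segmentation are logged.
    """
    samples = segments.sample_ids
    gdf = genes.df
    out = pd.DataFrame(
        np.nan, index=pd.Index(gdf["gene_id"], name="gene_id"), columns=samples
    )
    seg = segments.df.copy()
    seg["start0"] = seg["start"] - 1  # to 0-based half-open
    seg["end0"] = seg["end"]

    gene_chroms = set(gdf["chrom"].astype(str))
    for sample, sseg in seg.groupby("sample_id"):
        missing_chroms = gene_chroms - set(sseg["chromosome"].astype(str))
        if missing_chroms:
            logger.warning(
                "sample %s: no segments on chromosome(s) %s; gene values missing",
                sample, ",".join(sorted(missing_chroms)),
            )
        for chrom, cseg in sseg.groupby("chromosome"):
            cg = gdf[gdf["chrom"].astype(str) == str(chrom)]
            if cg.empty:
                continue
            gs = cg["start"].to_numpy()[:, None]
            ge = cg["end"].to_numpy()[:, None]
            ss = cseg["start0"].to_numpy()[None, :]
            se = cseg["end0"].to_numpy()[None, :]
            overlap = np.minimum(ge, se) - np.maximum(gs, ss)
            overlap = np.clip(overlap, 0, None)
            any_overlap = overlap.max(axis=1) > 0
            # largest overlap wins; ties -> earlier segment start
            order = np.lexsort((cseg["start0"].to_numpy()[None, :].repeat(len(cg), 0), -overlap), axis=1)
            best = order[:, 0]
            means = cseg["seg_mean"].to_numpy()[best]
            ids = cg["gene_id"].to_numpy()[any_overlap]
            out.loc[ids, sample] = means[any_overlap]
    return out


def call_states(ratios: pd.DataFrame, thresholds: CallThresholds = CallThresholds()) -> pd.DataFrame:
    """Five-state call per gene per sample; NaN ratios stay missing."""
    r = ratios.to_numpy(dtype=float)
    calls = np.full(r.shape, "diploid", dtype=object)
    calls[r <= thresholds.t_hetdel] = "hetdel"
    calls[r <= thresholds.t_homdel] = "homdel"
    gain = (r >= thresholds.t_gain) & (r < thresholds.t_amp)
    calls[gain] = "gain"
    calls[r >= thresholds.t_amp] = "amp"
    calls[~np.isfinite(r)] = None
    return pd.DataFrame(calls, index=ratios.index, columns=ratios.columns)


def significant_changes(calls: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask of per-sample significant changes (amp or homdel)."""
    return calls.isin(["amp", "homdel"])


def recurrent_genes(calls: pd.DataFrame, q_max: float = 0.01) -> pd.DataFrame:
    """Recurrently amplified / homozygously deleted genes.

    For each gene and each significant state, the number of samples in
    that state is tested against the cohort-wide background rate of the
    state (binomial upper tail), BH-adjusted across all gene x state
    tests. A gene is reported when q < q_max and its frequency exceeds
    the background. Zero background with nonzero gene rate uses a floor
    of 1/(2 * n_samples * n_genes).

    Returns a DataFrame with columns ``gene_id``, ``state`` (amp/del),
    ``n_altered``, ``n_samples``, ``frequency``, ``p``, ``q``.
    """
    n_samples = calls.shape[1]
    if n_samples < 10:
        raise ValueError(f"recurrence test needs >=10 samples, got {n_samples}")
    n_genes = calls.shape[0]
    observed = calls.notna()
    rows = []
    for state, label in (("amp", "amp"), ("homdel", "del")):
        is_state = (calls == state).to_numpy()
        total_cells = int(observed.to_numpy().sum())
        background = is_state.sum() / total_cells if total_cells else 0.0
        if background == 0.0:
            background = 1.0 / (2.0 * n_samples * n_genes)
        k = is_state.sum(axis=1)
        n_obs = observed.to_numpy().sum(axis=1)
        p = stats.binom.sf(k - 1, n_obs, background)
        freq = np.divide(k, n_obs, out=np.zeros(len(k)), where=n_obs > 0)
        for gid, ki, ni, fi, pi in zip(calls.index, k, n_obs, freq, p):
            rows.append((gid, label, int(ki), int(ni), fi, pi, background))
    table = pd.DataFrame(
        rows, columns=["gene_id", "state", "n_altered", "n_samples", "frequency", "p", "background"]
    )
    table["q"] = bh_adjust(table["p"].to_numpy())
    hits = table[(table["q"] < q_max) & (table["frequency"] > table["background"]) & (table["n_altered"] > 0)]
    return hits.drop(columns="background").sort_values(["state", "q", "gene_id"]).reset_index(drop=True)


def recurrent_sets(recurrent: pd.DataFrame) -> tuple[set, set]:
    """(amplified gene ids, deleted gene ids) from a recurrence table."""
    amp = set(recurrent.loc[recurrent["state"] == "amp", "gene_id"])
    dele = set(recurrent.loc[recurrent["state"] == "del", "gene_id"])
    return amp, dele
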