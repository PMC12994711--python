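"""Gene-level outlier calls from per-population window statistics.

The scan logic: within each population and statistic, windows are ranked
ascending (rank 1 = lowest value, i.e. most extreme for the low tails of
Tajima's D and Fay & Wu's H, ties sharing the minimum rank of the tied
block); each gene receives the minimum rank over all windows overlapping its
interval by at least 1 bp; a gene is *extreme* when that rank falls within
the lowest ``tail_quantile`` of the ranked-window count (boundary
inclusive).  A gene is a *concurrent hit* when it is extreme in at least
``concurrence_min_populations`` populations for every statistic considered.

The diversity comparison resamples background genes: per iteration a
background subset matching the candidate-set size is drawn without
replacement and a two-sided Wilcoxon rank-sum test compares median per-bp
nucleotide diversity; the full p-value vector is returned together with a
pooled candidates-vs-all-background test rather than a single manufactured
summary number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScanConfig",
    "ConsistencyError",
    "rank_windows",
    "min_rank_per_gene",
    "tag_extreme",
    "scan_population",
    "concurrence",
    "gene_median_pi",
    "pi_background_comparison",
]

SCAN_STATISTICS = ("tajimas_d", "fay_wu_h")


class ConsistencyError(ValueError):
    """Population sets differ across statistics."""


@dataclass(frozen=True)
class ScanConfig:
    """Tail, concurrence and resampling parameters of the outlier scan.

    ``tail_unit`` selects the ambiguity left open by rank-tail scans: with
    ``"windows"`` (default) a gene is extreme when its best window sits in
    the window-level 5% tail; with ``"genes"`` the quantile is taken over
    the genes' min-ranks instead.
    """

    tail_quantile: float = 0.05
    concurrence_min_populations: int = 10
    resample_iterations: int = 1000
    statistics: tuple = SCAN_STATISTICS
    tail_unit: str = "windows"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_quantile < 1.0:
            raise ValueError(f"tail_quantile must be in (0, 1), got {self.tail_quantile}")
        if self.concurrence_min_populations < 1:
            raise ValueError("concurrence_min_populations must be >= 1")
        if self.resample_iterations < 1:
            raise ValueError("resample_iterations must be >= 1")
        stats_ = tuple(self.statistics)
        if not stats_ or any(s not in SCAN_STATISTICS for s in stats_):
            raise ValueError(f"statistics must be a non-empty subset of {SCAN_STATISTICS}")
        object.__setattr__(self, "statistics", stats_)
        if self.tail_unit not in ("windows", "genes"):
            raise ValueError("tail_unit must be 'windows' or 'genes'")


def rank_windows(window_stats: pd.DataFrame, statistic: str) -> pd.DataFrame:
    """Ascending min-tie ranks of one statistic within one population.

    Missing values (windows with no defined statistic) are excluded from
    ranking and keep a missing rank.
    """
    if statistic not in window_stats.columns:
        raise KeyError(f"statistic column {statistic!r} absent from window table")
    out = window_stats.copy()
    out["rank"] = out[statistic].rank(method="min", na_option="keep")
    return out


def min_rank_per_gene(ranked: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Each gene's minimum window rank over >= 1 bp overlaps.

    Genes overlapping no ranked window get a missing rank.  The returned
    table also carries ``n_ranked_windows``, the population-wide count of
    ranked (non-missing) windows, which defines the tail threshold.
    """
    n_ranked = int(ranked["rank"].notna().sum())
    rows = []
    by_chrom = {
        chrom: grp.sort_values("start").reset_index(drop=True)
        for chrom, grp in ranked.groupby("chrom")
    }
    for gene_row in genes.itertuples(index=False):
        grp = by_chrom.get(gene_row.chrom)
        min_rank = math.nan
        if grp is not None:
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            mask = (starts < gene_row.end) & (ends > gene_row.start)
            ranks = grp.loc[mask, "rank"]
            if ranks.notna().any():
                min_rank = float(ranks.min())
        rows.append(
            {
                "gene": gene_row.gene,
                "chrom": gene_row.chrom,
                "min_rank": min_rank,
                "n_ranked_windows": n_ranked,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "chrom", "min_rank", "n_ranked_windows"])


def tag_extreme(gene_ranks: pd.DataFrame, config: ScanConfig) -> pd.DataFrame:
    """Flag genes whose min-rank falls in the lower tail (inclusive)."""
    out = gene_ranks.copy()
    if config.tail_unit == "windows":
        threshold = np.ceil(config.tail_quantile * out["n_ranked_windows"])
    else:  # quantile over the genes' min-ranks
        n_genes_ranked = int(out["min_rank"].notna().sum())
        gene_rank = out["min_rank"].rank(method="min", na_option="keep")
        threshold = np.ceil(config.tail_quantile * n_genes_ranked)
        out["is_extreme"] = gene_rank.le(threshold).fillna(False)
        return out
    out["is_extreme"] = out["min_rank"].le(threshold).fillna(False)
    return out


def scan_population(
    window_stats: pd.DataFrame,
    genes: pd.DataFrame,
    config: ScanConfig,
    population: str = "pop",
) -> pd.DataFrame:
    """Rank -> min-rank -> tail-tag for every configured statistic."""
    frames = []
    for statistic in config.statistics:
        ranked = rank_windows(window_stats, statistic)
        gene_ranks = tag_extreme(min_rank_per_gene(ranked, genes), config)
        gene_ranks.insert(0, "population", population)
        gene_ranks.insert(2, "statistic", statistic)
        frames.append(gene_ranks)
    return pd.concat(frames, ignore_index=True)


def concurrence(records: pd.DataFrame, config: ScanConfig) -> pd.DataFrame:
    """Cross-population extreme counts and the final concurrent-hit calls.

    ``records`` concatenates :func:`scan_population` outputs across
    populations.  A gene is a concurrent hit iff its extreme-population
    count reaches ``concurrence_min_populations`` for *every* statistic in
    the configuration.
    """
    pops_by_stat = {
        s: frozenset(records.loc[records["statistic"] == s, "population"].unique())
        for s in config.statistics
    }
    if len(set(pops_by_stat.values())) > 1:
        raise ConsistencyError(
            f"population sets differ across statistics: "
            f"{ {s: sorted(p) for s, p in pops_by_stat.items()} }"
        )
    counts = (
        records[records["statistic"].isin(config.statistics)]
        .groupby(["gene", "statistic"])["is_extreme"]
        .sum()
        .unstack(fill_value=0)
        .astype(int)
    )
    out = counts.rename(columns={s: f"count_{s}" for s in config.statistics}).reset_index()
    hit = np.ones(len(out), dtype=bool)
    for s in config.statistics:
        hit &= out[f"count_{s}"].to_numpy() >= config.concurrence_min_populations
    out["concurrent_hit"] = hit
    return out.sort_values("gene").reset_index(drop=True)


def gene_median_pi(window_stats: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Per-gene median per-bp nucleotide diversity over overlapping windows.

    ``window_stats`` may pool several populations' window tables; all
    overlapping windows contribute to the median.  Genes with no overlapping
    window are absent from the result.
    """
    ws = window_stats.copy()
    ws["pi_per_bp"] = ws["pi"] / (ws["end"] - ws["start"])
    values: dict[str, float] = {}
    by_chrom = {chrom: grp.reset_index(drop=True) for chrom, grp in ws.groupby("chrom")}
    for gene_row in genes.itertuples(index=False):
        grp = by_chrom.get(gene_row.chrom)
        if grp is None:
            continue
        mask = (grp["start"].to_numpy() < gene_row.end) & (
            grp["end"].to_numpy() > gene_row.start
        )
        if mask.any():
            values[gene_row.gene] = float(grp.loc[mask, "pi_per_bp"].median())
    return pd.Series(values, name="pi_per_bp")


def pi_background_comparison(
    gene_pi: pd.Series,
    candidates: Sequence[str],
    config: ScanConfig,
    rng: np.random.Generator | None = None,
) -> dict:
    """Resampled Wilcoxon comparison of candidate vs background diversity.

    Per iteration, a background subset of the candidate-set size is drawn
    without replacement and compared two-sided.  Returns the p-value vector,
    its median, the fraction of iterations with the candidate median below
    the background-subset median, and one pooled candidates-vs-all-background
    test.
    """
    rng = rng or np.random.default_rng(config.seed)
    candidates = [g for g in candidates if g in gene_pi.index]
    if not candidates:
        raise ValueError("no candidate gene has a diversity value")
    cand = gene_pi.loc[candidates].to_numpy(dtype=float)
    background = gene_pi.drop(index=candidates)
    if len(background) < len(candidates):
        raise ValueError(
            f"background ({len(background)}) smaller than candidate set ({len(candidates)})"
        )
    bg = background.to_numpy(dtype=float)
    B = config.resample_iterations
    p_values = np.empty(B)
    lower = np.empty(B, dtype=bool)
    for i in range(B):
        subset = bg[rng.choice(bg.size, size=cand.size, replace=False)]
        res = stats.mannwhitneyu(cand, subset, alternative="two-sided")
        p_values[i] = res.pvalue
        lower[i] = np.median(cand) < np.median(subset)
    pooled = stats.mannwhitneyu(cand, bg, alternative="two-sided")
    return {
        "p_values": p_values.tolist(),
        "median_p": float(np.median(p_values)),
        "fraction_candidate_lower": float(lower.mean()),
        "pooled_p": float(pooled.pvalue),
        "candidate_median": float(np.median(cand)),
        "background_median": float(np.median(bg)),
        "n_candidates": int(cand.size),
        "n_background": int(bg.size),
    }
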