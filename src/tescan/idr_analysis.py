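"""Consensus IDR intervals, sequence descriptors, and enrichment statistics.

An intrinsically disordered region (IDR) is a run of at least 30 consecutive
reference residues whose alignment columns are called disordered in at least
half of the species carrying a residue there.  For each IDR the module
computes, per ortholog, three sequence descriptors:

* FCR   -- fraction of charged residues ``(n+ + n-) / N``;
* NCPR  -- net charge per residue ``(n+ - n-) / N``;
* SHD   -- sequence hydropathy decoration,
           ``(1/N) * sum_{i<j} (lambda_i + lambda_j) (j - i)^(-beta)``,
           a distance-weighted measure of hydrophobic patterning.

Ensemble descriptors (conformational entropy per residue Sconf/N and the
Flory scaling exponent nu) cannot be computed from sequence alone and are
joined from an externally supplied table, never computed here.

Statistical helpers cover the length-weighted binomial enrichment test for
positively selected sites inside IDRs, Wilcoxon rank-sum group comparisons
(exact for small groups), Kendall's tau for constraint-feature correlations
and Pearson's r for cross-predictor disorder-fraction agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KYTE_DOOLITTLE_01",
    "FeatureConfig",
    "IDRInterval",
    "consensus_idrs",
    "fcr_ncpr",
    "shd",
    "extract_ortholog_segment",
    "idr_feature_table",
    "binomial_enrichment",
    "compare_groups",
    "constraint_feature_correlation",
    "disorder_fraction_correlation",
]

# Kyte-Doolittle hydropathy rescaled to [0, 1] via (kd + 4.5) / 9
_KD_RAW = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
KYTE_DOOLITTLE_01 = {aa: (v + 4.5) / 9.0 for aa, v in _KD_RAW.items()}


def _default_scale() -> Mapping[str, float]:
    return dict(KYTE_DOOLITTLE_01)


@dataclass(frozen=True)
class FeatureConfig:
    """Residue sets and the hydropathy scale behind the IDR descriptors.

    Histidine is excluded from the charged set by default (its side chain is
    mostly neutral at physiological pH); set ``include_histidine`` to count
    it as positive.
    """

    positive_residues: frozenset = frozenset("KR")
    negative_residues: frozenset = frozenset("DE")
    hydropathy_scale: Mapping[str, float] = field(default_factory=_default_scale)
    shd_exponent: float = 1.0
    include_histidine: bool = False

    def __post_init__(self) -> None:
        if self.shd_exponent <= 0:
            raise ValueError("shd_exponent must be positive")
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.hydropathy_scale)
        if missing:
            raise ValueError(f"hydropathy scale lacks residues {sorted(missing)}")

    @property
    def effective_positive(self) -> frozenset:
        if self.include_histidine:
            return self.positive_residues | {"H"}
        return frozenset(self.positive_residues)


@dataclass(frozen=True)
class IDRInterval:
    """A consensus disorder interval, 1-based inclusive on the reference."""

    protein: str
    start: int
    end: int
    has_positive_site: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ValueError(f"invalid IDR interval ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


def _species_column_maps(msa: Sequence[tuple[str, str]]) -> dict[str, dict[int, int]]:
    """Per species: 1-based alignment column -> 1-based ungapped residue."""
    out: dict[str, dict[int, int]] = {}
    for name, seq in msa:
        mapping: dict[int, int] = {}
        residue = 0
        for col, ch in enumerate(seq, start=1):
            if ch != "-":
                residue += 1
                mapping[col] = residue
        out[name] = mapping
    return out


def consensus_idrs(
    disorder: pd.DataFrame,
    msa: Sequence[tuple[str, str]],
    reference_id: str,
    min_len: int = 30,
    min_species_frac: float = 0.5,
) -> list[IDRInterval]:
    """Ortholog-consensus IDR intervals on the reference protein.

    ``disorder`` is a long table (species, residue, disordered) with residue
    numbers in each species' own ungapped coordinates.  Per alignment column
    the disorder fraction is computed over species with a residue at that
    column; columns at fraction >= ``min_species_frac`` (boundary inclusive)
    are consensus-disordered, and maximal runs of >= ``min_len`` consensus
    reference residues become intervals.  Species contributing only gaps add
    nothing, so the output is invariant to species order and all-gap rows.
    """
    names = [name for name, _ in msa]
    if reference_id not in names:
        raise KeyError(f"reference {reference_id!r} not present in alignment")
    col_maps = _species_column_maps(msa)
    n_cols = len(msa[0][1])

    calls: dict[str, set[int]] = {name: set() for name in names}
    for species, residue, flag in disorder[["species", "residue", "disordered"]].itertuples(
        index=False
    ):
        if species in calls and flag:
            calls[species].add(int(residue))

    protein = disorder["protein"].iloc[0] if "protein" in disorder.columns and len(disorder) else reference_id
    ref_map = col_maps[reference_id]

    consensus_cols = np.zeros(n_cols + 1, dtype=bool)  # 1-based
    for col in range(1, n_cols + 1):
        present = 0
        disordered = 0
        for name in names:
            residue = col_maps[name].get(col)
            if residue is None:
                continue
            present += 1
            if residue in calls[name]:
                disordered += 1
        if present and disordered / present >= min_species_frac:
            consensus_cols[col] = True

    # runs over reference residues (reference non-gap columns, in order)
    intervals: list[IDRInterval] = []
    run_start: int | None = None
    prev_res: int | None = None
    for col, res in ref_map.items():
        if consensus_cols[col]:
            if run_start is None:
                run_start = res
            prev_res = res
        else:
            if run_start is not None and prev_res - run_start + 1 >= min_len:
                intervals.append(IDRInterval(protein=str(protein), start=run_start, end=prev_res))
            run_start = None
    if run_start is not None and prev_res - run_start + 1 >= min_len:
        intervals.append(IDRInterval(protein=str(protein), start=run_start, end=prev_res))
    return intervals


def fcr_ncpr(sequence: str, config: FeatureConfig | None = None) -> tuple[float, float]:
    """Fraction of charged residues and net charge per residue."""
    config = config or FeatureConfig()
    if not sequence:
        raise ValueError("empty sequence")
    pos = sum(1 for c in sequence if c in config.effective_positive)
    neg = sum(1 for c in sequence if c in config.negative_residues)
    N = len(sequence)
    return (pos + neg) / N, (pos - neg) / N


def shd(sequence: str, config: FeatureConfig | None = None) -> float:
    """Sequence hydropathy decoration (symmetric under sequence reversal)."""
    config = config or FeatureConfig()
    N = len(sequence)
    if N < 2:
        raise ValueError("SHD needs at least 2 residues")
    try:
        lam = np.array([config.hydropathy_scale[c] for c in sequence], dtype=float)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} missing from hydropathy scale") from None
    beta = config.shd_exponent
    total = 0.0
    for d in range(1, N):
        total += float(np.sum(lam[:-d] + lam[d:])) * d ** (-beta)
    return total / N


def extract_ortholog_segment(
    msa: Sequence[tuple[str, str]],
    reference_id: str,
    species: str,
    start: int,
    end: int,
) -> str:
    """A species' ungapped subsequence over a reference residue interval."""
    from .sel_sites import reference_to_column

    ref_to_col = reference_to_column(msa, reference_id)
    seqs = dict(msa)
    if species not in seqs:
        raise KeyError(f"species {species!r} not present in alignment")
    cols = [ref_to_col[r] for r in range(start, end + 1)]
    return "".join(
        seqs[species][c - 1] for c in cols if seqs[species][c - 1] != "-"
    )


ENSEMBLE_FEATURES = ("sconf_per_n", "nu")
SEQUENCE_FEATURES = ("fcr", "ncpr", "shd")


def idr_feature_table(
    idrs: Sequence[IDRInterval],
    msa: Sequence[tuple[str, str]],
    reference_id: str,
    config: FeatureConfig | None = None,
    external: pd.DataFrame | None = None,
    min_segment_len: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-IDR, per-ortholog features plus across-ortholog mean and SD.

    FCR/NCPR/SHD are computed from each ortholog's MSA-projected subsequence
    (gaps removed); Sconf/N and nu are joined from ``external`` (columns
    protein, species, idr_start, idr_end, sconf_per_n, nu) by maximal
    interval overlap, when provided.  Ortholog segments shorter than
    ``min_segment_len`` residues are skipped.  The SD uses the n-1
    denominator; the across-ortholog SD is the single per-IDR measure of
    feature conservation used downstream.
    """
    config = config or FeatureConfig()
    rows = []
    for idr in idrs:
        for species, _seq in msa:
            segment = extract_ortholog_segment(msa, reference_id, species, idr.start, idr.end)
            if len(segment) < min_segment_len:
                continue
            fcr, ncpr = fcr_ncpr(segment, config)
            row = {
                "protein": idr.protein,
                "idr_start": idr.start,
                "idr_end": idr.end,
                "species": species,
                "fcr": fcr,
                "ncpr": ncpr,
                "shd": shd(segment, config),
            }
            rows.append(row)
    per_ortholog = pd.DataFrame(
        rows,
        columns=["protein", "idr_start", "idr_end", "species"] + list(SEQUENCE_FEATURES),
    )

    features = list(SEQUENCE_FEATURES)
    if external is not None and len(per_ortholog):
        ext = external.copy()
        joined = []
        for (protein, start, end), group in per_ortholog.groupby(
            ["protein", "idr_start", "idr_end"]
        ):
            cand = ext[ext["protein"] == protein]
            if cand.empty:
                joined.append(group.assign(sconf_per_n=np.nan, nu=np.nan))
                continue
            overlap = np.minimum(cand["idr_end"], end) - np.maximum(cand["idr_start"], start) + 1
            cand = cand.assign(_overlap=overlap)
            cand = cand[cand["_overlap"] > 0]
            if cand.empty:
                joined.append(group.assign(sconf_per_n=np.nan, nu=np.nan))
                continue
            best = cand.loc[cand["_overlap"] == cand["_overlap"].max()]
            per_species = best.set_index("species")[list(ENSEMBLE_FEATURES)]
            per_species = per_species[~per_species.index.duplicated()]
            joined.append(group.join(per_species, on="species"))
        per_ortholog = pd.concat(joined, ignore_index=True)
        features += list(ENSEMBLE_FEATURES)

    if per_ortholog.empty:
        summary = pd.DataFrame(columns=["protein", "idr_start", "idr_end", "feature", "mean", "sd"])
        return per_ortholog, summary

    melted = per_ortholog.melt(
        id_vars=["protein", "idr_start", "idr_end", "species"],
        value_vars=features,
        var_name="feature",
    )
    summary = (
        melted.groupby(["protein", "idr_start", "idr_end", "feature"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return per_ortholog, summary


def binomial_enrichment(
    k_in_idr: int,
    m_total: int,
    idr_length_total: int,
    analyzed_length_total: int,
    alternative: str = "greater",
    mid_p: bool = False,
) -> float:
    """Exact binomial test for selected-site enrichment inside IDRs.

    Successes are the ``k_in_idr`` sites falling in IDRs among ``m_total``
    selected sites; the success probability is the length ratio
    ``idr_length_total / analyzed_length_total``.  One-sided ``greater`` by
    default (the enrichment hypothesis); ``two-sided`` and ``less`` are
    available.

    The exact tail probability is conservative (stochastically larger than
    uniform under the null) because the test statistic is discrete.
    ``mid_p`` gives Lancaster's mid-p variant -- half the probability of the
    observed count plus the strict tail -- which is approximately uniform
    under the null and is the appropriate quantity for calibration studies;
    it is available for the one-sided alternatives only.
    """
    if not 0 <= k_in_idr <= m_total:
        raise ValueError(f"need 0 <= k ({k_in_idr}) <= m ({m_total})")
    if analyzed_length_total <= 0:
        raise ValueError("analyzed length must be positive")
    p0 = idr_length_total / analyzed_length_total
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"success probability {p0} outside (0, 1)")
    if m_total == 0:
        return 1.0
    if mid_p:
        if alternative == "greater":
            return float(
                stats.binom.sf(k_in_idr, m_total, p0)
                + 0.5 * stats.binom.pmf(k_in_idr, m_total, p0)
            )
        if alternative == "less":
            return float(
                stats.binom.cdf(k_in_idr - 1, m_total, p0)
                + 0.5 * stats.binom.pmf(k_in_idr, m_total, p0)
            )
        raise ValueError("mid_p is defined for one-sided alternatives only")
    return float(
        stats.binomtest(k_in_idr, m_total, p0, alternative=alternative).pvalue
    )


def compare_groups(
    selected: Sequence[float], background: Sequence[float], exact_max_n: int = 20
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of a feature between IDR groups.

    Exact enumeration for group sizes up to ``exact_max_n`` (and no ties),
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(selected, dtype=float)
    b = np.asarray(background, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = (
        "exact"
        if a.size <= exact_max_n and b.size <= exact_max_n and np.unique(np.r_[a, b]).size == a.size + b.size
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "p": float(res.pvalue),
        "statistic": float(res.statistic),
        "median_selected": float(np.median(a)),
        "median_background": float(np.median(b)),
        "n_selected": int(a.size),
        "n_background": int(b.size),
        "method": method,
    }


def constraint_feature_correlation(
    fraction_negative: Sequence[float], feature: Sequence[float]
) -> tuple[float, float]:
    """Kendall's tau-b between per-IDR purifying fraction and a feature."""
    x = np.asarray(fraction_negative, dtype=float)
    y = np.asarray(feature, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch ({x.size} vs {y.size})")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def disorder_fraction_correlation(
    fractions_a: Sequence[float], fractions_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between per-protein disorder fractions from two
    annotation sources; (nan, nan) when either vector is constant."""
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"length mismatch ({a.size} vs {b.size})")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan, math.nan
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
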