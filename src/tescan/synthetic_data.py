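"""Synthetic inputs with known ground truth for the whole pipeline.

Two generators live here.

**Population side** -- a neutral Kingman coalescent per non-recombining locus
(pairwise coalescence rate ``k(k-1)/2``), with infinite-sites mutations placed
on branches at rate ``theta/2`` per unit branch length.  Loci are short
(default 2.5 kb, ``theta = 2.5`` i.e. 0.001/bp, human-like) and coalesce
independently: free recombination between loci, none within.  A 50-kb scan
window therefore pools ~20 independent genealogies, which is what keeps the
neutral null of windowed D and H well behaved at that physical scale.

Selective sweeps are modelled as a star-merger distortion: at backward time
``sweep_age`` each surviving lineage is captured into a single star ancestor
with probability ``sweep_strength * (1 - sweep_escape)``; the escaped
lineages (at least one whenever two or more survive) continue coalescing
neutrally together with the star ancestor.  Mutations on the star ancestor's
upper branch then segregate at frequency near ``n - 1``: the high-frequency
derived excess that drives Fay & Wu's H negative, while the truncated lower
tree yields the singleton excess that drives Tajima's D negative.
``sweep_escape`` plays the role of recombinational escape from a hard sweep
across a ~50-kb window.

**Proteome side** -- ortholog protein families with disorder-biased segments,
planted positively/negatively selected sites, noisy per-species disorder
calls, per-method site-call tables (BEB/FUBAR/MEME/FEL/SLAC) with chosen
sensitivity/specificity, and synthetic ensemble features (Sconf/N, nu) drawn
as noisy monotone functions of SHD so the downstream comparisons have signal.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .popgen_stats import PolarizedWindow
from .sel_sites import CALLS_COLUMNS, POSITIVE_METHODS, ConsensusRule

__all__ = [
    "ConfigurationError",
    "SimPopConfig",
    "SimProteomeConfig",
    "SimulatedProteome",
    "simulate_neutral_window",
    "simulate_sweep_window",
    "simulate_window",
    "simulate_populations",
    "simulate_ortholog_proteins",
    "sample_site_counts",
    "tile_genes",
    "write_population_vcf",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


# --------------------------------------------------------------------------
# population genetics side
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimPopConfig:
    """One population's simulation parameters.

    ``theta`` is the population-scaled mutation rate per locus of
    ``window_length_bp``; ``sweep_age`` is in coalescent time units;
    ``sweep_strength`` is the fraction of lineages pulled into the star
    merger, thinned by the recombinational-escape fraction ``sweep_escape``.
    """

    n_haplotypes: int = 30
    theta: float = 2.5
    n_windows: int = 3000
    window_length_bp: int = 2500
    sweep_windows: frozenset = frozenset()
    sweep_age: float = 0.05
    sweep_strength: float = 1.0
    sweep_escape: float = 0.1
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ConfigurationError(f"n_haplotypes must be >= 2, got {self.n_haplotypes}")
        if self.theta < 0:
            raise ConfigurationError(f"theta must be >= 0, got {self.theta}")
        if self.n_windows < 1 or self.window_length_bp < 1:
            raise ConfigurationError("n_windows and window_length_bp must be positive")
        if not 0.0 <= self.sweep_strength <= 1.0:
            raise ConfigurationError(f"sweep_strength must be in [0, 1], got {self.sweep_strength}")
        if not 0.0 <= self.sweep_escape < 1.0:
            raise ConfigurationError(f"sweep_escape must be in [0, 1), got {self.sweep_escape}")
        if self.sweep_age < 0:
            raise ConfigurationError(f"sweep_age must be >= 0, got {self.sweep_age}")
        object.__setattr__(self, "sweep_windows", frozenset(int(w) for w in self.sweep_windows))
        for w in self.sweep_windows:
            if not 0 <= w < self.n_windows:
                raise ConfigurationError(f"sweep window index {w} outside [0, {self.n_windows})")

    @property
    def chrom_length(self) -> int:
        return self.n_windows * self.window_length_bp


def _window_rng(config: SimPopConfig, window_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(window_index)])


def _genealogy(
    n: int,
    rng: np.random.Generator,
    sweep_age: float | None = None,
    sweep_strength: float = 0.0,
    sweep_escape: float = 0.1,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Branch lengths and leaf sets of one (possibly sweep-distorted) tree.

    Returns all branches below the grand MRCA as parallel arrays: a float
    array of lengths and a list of leaf-index arrays (the haplotypes that
    inherit a mutation on that branch).
    """
    birth = [0.0] * n
    leaves: list[np.ndarray] = [np.array([i]) for i in range(n)]
    t = 0.0
    out_len: list[float] = []
    out_leaves: list[np.ndarray] = []

    def coalesce(t: float) -> None:
        k = len(leaves)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a_leaves, b_leaves = leaves[i], leaves[j]
        a_birth, b_birth = birth[i], birth[j]
        for idx in sorted((i, j), reverse=True):
            leaves.pop(idx)
            birth.pop(idx)
        out_len.append(t - a_birth)
        out_leaves.append(a_leaves)
        out_len.append(t - b_birth)
        out_leaves.append(b_leaves)
        leaves.append(np.concatenate([a_leaves, b_leaves]))
        birth.append(t)

    sweeping = sweep_age is not None and sweep_strength > 0.0
    while len(leaves) > 1:
        k = len(leaves)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if sweeping and t + wait >= sweep_age:
            t = sweep_age
            break
        t += wait
        coalesce(t)

    if sweeping and len(leaves) >= 2:
        capture = rng.random(len(leaves)) < sweep_strength * (1.0 - sweep_escape)
        if capture.all():
            # recombinational escape: a completed sweep in a physical window
            # always leaves at least one escaped lineage
            capture[int(rng.integers(len(leaves)))] = False
        caught = np.flatnonzero(capture)
        if caught.size >= 2:
            star_leaves = np.concatenate([leaves[i] for i in caught])
            for i in caught[::-1]:
                out_len.append(t - birth[i])
                out_leaves.append(leaves[i])
                leaves.pop(int(i))
                birth.pop(int(i))
            leaves.append(star_leaves)
            birth.append(t)
        while len(leaves) > 1:
            k = len(leaves)
            t += rng.exponential(2.0 / (k * (k - 1)))
            coalesce(t)

    return np.asarray(out_len, dtype=float), out_leaves


def _mutate(
    lengths: np.ndarray,
    leaf_sets: list[np.ndarray],
    theta: float,
    n: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Place infinite-sites mutations; returns one carrier set per site."""
    total = float(lengths.sum())
    S = int(rng.poisson(theta / 2.0 * total)) if total > 0 and theta > 0 else 0
    if S == 0:
        return []
    cum = np.cumsum(lengths)
    idx = np.searchsorted(cum, rng.random(S) * total, side="right")
    idx = np.minimum(idx, len(lengths) - 1)
    return [leaf_sets[i] for i in idx if 0 < leaf_sets[i].size < n]


def _counts_for_window(config: SimPopConfig, window_index: int, sweep: bool) -> tuple[int, ...]:
    rng = _window_rng(config, window_index)
    carriers = _site_carriers(config, rng, sweep)
    return tuple(sorted(c.size for c in carriers))


def _site_carriers(
    config: SimPopConfig, rng: np.random.Generator, sweep: bool
) -> list[np.ndarray]:
    lengths, leaf_sets = _genealogy(
        config.n_haplotypes,
        rng,
        sweep_age=config.sweep_age if sweep else None,
        sweep_strength=config.sweep_strength if sweep else 0.0,
        sweep_escape=config.sweep_escape,
    )
    return _mutate(lengths, leaf_sets, config.theta, config.n_haplotypes, rng)


def simulate_neutral_window(config: SimPopConfig, window_index: int) -> PolarizedWindow:
    """Fully polarized derived-allele counts from a neutral coalescent."""
    if window_index in config.sweep_windows:
        raise ConfigurationError(f"window {window_index} is a sweep window")
    if not 0 <= window_index < config.n_windows:
        raise ConfigurationError(f"window index {window_index} outside [0, {config.n_windows})")
    start = window_index * config.window_length_bp
    return PolarizedWindow(
        chrom=config.chrom,
        start=start,
        end=start + config.window_length_bp,
        n=config.n_haplotypes,
        derived_counts=_counts_for_window(config, window_index, sweep=False),
    )


def simulate_sweep_window(config: SimPopConfig, window_index: int) -> PolarizedWindow:
    """As neutral, plus the star-merger sweep distortion at ``sweep_age``."""
    if window_index not in config.sweep_windows:
        raise ConfigurationError(f"window {window_index} is not in sweep_windows")
    start = window_index * config.window_length_bp
    return PolarizedWindow(
        chrom=config.chrom,
        start=start,
        end=start + config.window_length_bp,
        n=config.n_haplotypes,
        derived_counts=_counts_for_window(config, window_index, sweep=True),
    )


def simulate_window(config: SimPopConfig, window_index: int) -> PolarizedWindow:
    if window_index in config.sweep_windows:
        return simulate_sweep_window(config, window_index)
    return simulate_neutral_window(config, window_index)


_BASES = "ACGT"


def write_population_vcf(config: SimPopConfig, path: str | Path, population: str = "pop") -> int:
    """Write one population's phased diploid VCF with ``INFO/AA``.

    Haplotypes are paired into diploid samples (``n_haplotypes`` must be
    even).  REF/ALT orientation is randomized so that the ancestral allele is
    sometimes ALT, exercising downstream polarity flips.  Returns the number
    of variant records written.
    """
    if config.n_haplotypes % 2 != 0:
        raise ConfigurationError("VCF output needs an even n_haplotypes (diploid samples)")
    n = config.n_haplotypes
    samples = [f"{population}_ind{i:03d}" for i in range(n // 2)]
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={config.chrom},length={config.chrom_length}>",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    records: list[str] = []
    n_records = 0
    for w in range(config.n_windows):
        rng = _window_rng(config, w)
        carriers = _site_carriers(config, rng, sweep=w in config.sweep_windows)
        S = len(carriers)
        if S == 0:
            continue
        start = w * config.window_length_bp
        offsets = rng.choice(config.window_length_bp, size=S, replace=False)
        order = np.argsort(offsets)
        anc_idx = rng.integers(0, 4, size=S)
        der_shift = rng.integers(1, 4, size=S)
        flip = rng.random(S) < 0.5
        for s in order:
            pos = start + int(offsets[s]) + 1  # VCF POS is 1-based
            anc = _BASES[int(anc_idx[s])]
            der = _BASES[(int(anc_idx[s]) + int(der_shift[s])) % 4]
            hap = np.zeros(n, dtype=int)
            hap[carriers[s]] = 1
            if flip[s]:
                ref, alt = der, anc
                hap = 1 - hap
            else:
                ref, alt = anc, der
            gts = "\t".join(f"{hap[2 * i]}|{hap[2 * i + 1]}" for i in range(n // 2))
            records.append(
                f"{config.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tAA={anc}\tGT\t{gts}"
            )
            n_records += 1
    Path(path).write_text("\n".join(header + records) + "\n")
    return n_records


def tile_genes(
    chrom_length: int,
    gene_span: int = 50_000,
    margin: int = 10_000,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """One gene per ``gene_span`` block, inset by ``margin`` on both sides."""
    if gene_span <= 2 * margin:
        raise ConfigurationError("gene_span must exceed twice the margin")
    n_genes = chrom_length // gene_span
    rows = [
        {
            "chrom": chrom,
            "start": g * gene_span + margin,
            "end": (g + 1) * gene_span - margin,
            "gene": f"gene_{g:05d}",
        }
        for g in range(n_genes)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", index=False, header=False)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"]
    )


def simulate_populations(
    configs: Mapping[str, SimPopConfig],
    out_dir: str | Path,
    genes: pd.DataFrame | None = None,
) -> dict:
    """Write per-population VCFs, a genes BED and a ground-truth manifest.

    All populations must share chromosome geometry.  If ``genes`` is None, a
    default tiling of one gene per 50-kb block is used.  The manifest records
    the sweep windows and the genes they overlap, per population.
    """
    if not configs:
        raise ConfigurationError("at least one population is required")
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    geometries = {(c.chrom, c.chrom_length, c.window_length_bp) for c in configs.values()}
    if len(geometries) > 1:
        raise ConfigurationError("all populations must share chromosome geometry")
    any_cfg = next(iter(configs.values()))
    if genes is None:
        genes = tile_genes(any_cfg.chrom_length, chrom=any_cfg.chrom)
    if (genes["end"] > any_cfg.chrom_length).any() or (genes["start"] < 0).any():
        raise ConfigurationError("gene intervals fall outside the simulated chromosome")

    manifest: dict = {
        "chrom": any_cfg.chrom,
        "chrom_length": any_cfg.chrom_length,
        "window_length_bp": any_cfg.window_length_bp,
        "populations": {},
        "vcf": {},
        "genes_bed": str(out / "genes.bed"),
    }
    write_genes_bed(genes, out / "genes.bed")
    for pop, cfg in sorted(configs.items()):
        vcf_path = out / "vcf" / f"{pop}.vcf"
        n_rec = write_population_vcf(cfg, vcf_path, population=pop)
        sweep_windows = sorted(cfg.sweep_windows)
        wl = cfg.window_length_bp
        sweep_genes = sorted(
            set(
                genes.loc[
                    (genes["chrom"] == cfg.chrom)
                    & genes.apply(
                        lambda g: any(
                            g["start"] < (w + 1) * wl and g["end"] > w * wl
                            for w in sweep_windows
                        ),
                        axis=1,
                    ),
                    "gene",
                ]
            )
            if sweep_windows
            else []
        )
        manifest["populations"][pop] = {
            "seed": cfg.seed,
            "n_haplotypes": cfg.n_haplotypes,
            "theta": cfg.theta,
            "sweep_windows": sweep_windows,
            "sweep_genes": sweep_genes,
            "sweep_age": cfg.sweep_age,
            "sweep_strength": cfg.sweep_strength,
            "n_records": n_rec,
        }
        manifest["vcf"][pop] = str(vcf_path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# --------------------------------------------------------------------------
# proteome side
# --------------------------------------------------------------------------

# disorder-promoting vs order-promoting residue pools (rough mammalian
# composition bias; exact frequencies are not load-bearing)
_DISORDER_AA = np.array(list("SPEKGQDRATN"))
_ORDER_AA = np.array(list("LIVFMWYACHNTSGEDKRQP"))


@dataclass(frozen=True)
class SimProteomeConfig:
    """Ortholog-proteome generator parameters.

    ``idr_segments`` holds, per protein, 1-based inclusive ``(start, end,
    disorder_bias)`` tuples; ``planted_site_enrichment`` is the ratio of the
    per-residue positively-selected-site probability inside vs outside IDRs.
    """

    protein_lengths: tuple
    idr_segments: tuple
    n_species: int = 12
    planted_site_enrichment: float = 5.0
    site_rate: float = 0.0018
    negative_site_rate: float = 0.03
    method_sensitivity: float = 0.8
    method_specificity: float = 0.995
    divergence: float = 0.05
    selected_divergence: float = 0.35
    disorder_background: float = 0.05
    seed: int = 0
    reference_species: str = "sp00"

    def __post_init__(self) -> None:
        lengths = tuple(int(x) for x in self.protein_lengths)
        segs = tuple(
            tuple((int(a), int(b), float(bias)) for a, b, bias in per_protein)
            for per_protein in self.idr_segments
        )
        object.__setattr__(self, "protein_lengths", lengths)
        object.__setattr__(self, "idr_segments", segs)
        if len(segs) != len(lengths):
            raise ConfigurationError("idr_segments and protein_lengths must align")
        if self.n_species < 2:
            raise ConfigurationError("need at least 2 species")
        if self.planted_site_enrichment < 0:
            raise ConfigurationError("planted_site_enrichment must be >= 0")
        for p in (
            self.site_rate,
            self.negative_site_rate,
            self.method_sensitivity,
            self.method_specificity,
            self.divergence,
            self.selected_divergence,
            self.disorder_background,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability parameter {p} outside [0, 1]")
        for length, per_protein in zip(lengths, segs):
            prev_end = 0
            for a, b, bias in per_protein:
                if not (1 <= a <= b <= length):
                    raise ConfigurationError(
                        f"IDR segment ({a}, {b}) outside protein of length {length}"
                    )
                if a <= prev_end:
                    raise ConfigurationError("IDR segments must be sorted and non-overlapping")
                if not 0.0 <= bias <= 1.0:
                    raise ConfigurationError("disorder_bias must be in [0, 1]")
                prev_end = b

    @property
    def n_proteins(self) -> int:
        return len(self.protein_lengths)

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_proteins: int = 60,
        n_species: int = 12,
        mean_length: int = 500,
        sd_length: int = 80,
        idr_fraction: float = 0.43,
        disorder_bias: float = 0.95,
        **overrides,
    ) -> "SimProteomeConfig":
        """Draw a realistic proteome geometry deterministically from ``seed``.

        Per-protein lengths are normal around ``mean_length``; each protein
        receives one to three disordered segments whose combined span targets
        a Beta-distributed per-protein IDR fraction with the requested mean.
        """
        rng = np.random.default_rng([int(seed), 777])
        lengths = np.clip(
            rng.normal(mean_length, sd_length, n_proteins).astype(int), 120, None
        )
        # Beta with mean idr_fraction and moderate spread
        a = 8.0 * idr_fraction
        b = 8.0 * (1.0 - idr_fraction)
        fractions = rng.beta(a, b, n_proteins)
        segments = []
        for L, frac in zip(lengths, fractions):
            total = max(30, int(round(frac * L)))
            total = min(total, L - 10)
            n_seg = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, total), size=n_seg - 1, replace=False)) if n_seg > 1 else np.array([], dtype=int)
            pieces = np.diff(np.concatenate([[0], cuts, [total]]))
            pieces = pieces[pieces >= 30]
            if pieces.size == 0:
                pieces = np.array([total])
            free = L - int(pieces.sum())
            gaps = rng.multinomial(free, np.ones(pieces.size + 1) / (pieces.size + 1))
            segs = []
            pos = 0
            for piece, gap in zip(pieces, gaps[:-1]):
                start = pos + int(gap) + 1
                end = start + int(piece) - 1
                segs.append((start, end, disorder_bias))
                pos = end
            segments.append(tuple(segs))
        return cls(
            protein_lengths=tuple(int(x) for x in lengths),
            idr_segments=tuple(segments),
            n_species=n_species,
            seed=seed,
            **overrides,
        )


@dataclass
class SimulatedProteome:
    """Generator output bundle: alignments, calls, disorder, truth."""

    config: SimProteomeConfig
    msas: dict  # protein -> list of (species, sequence), reference first
    disorder: pd.DataFrame  # protein, species, residue, disordered
    calls: pd.DataFrame  # protein, method, column, score, direction
    ensemble: pd.DataFrame  # protein, species, idr_start, idr_end, sconf_per_n, nu
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "msa").mkdir(parents=True, exist_ok=True)
        for protein in sorted(self.msas):
            lines = []
            for species, seq in self.msas[protein]:
                lines.append(f">{species}")
                lines.append(seq)
            (out / "msa" / f"{protein}.fasta").write_text("\n".join(lines) + "\n")
        self.disorder.to_csv(out / "disorder.tsv", sep="\t", index=False)
        self.calls.to_csv(out / "site_calls.tsv", sep="\t", index=False, float_format="%.6g")
        self.ensemble.to_csv(out / "ensemble.tsv", sep="\t", index=False, float_format="%.6g")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _idr_mask(length: int, segments: Sequence[tuple]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for a, b, _bias in segments:
        mask[a - 1 : b] = True
    return mask


def _shd_quick(lam: np.ndarray) -> float:
    # pairwise (lam_i + lam_j) / (j - i), averaged by sequence length
    N = lam.size
    if N < 2:
        return 0.0
    total = 0.0
    for d in range(1, N):
        total += np.sum(lam[:-d] + lam[d:]) / d
    return float(total / N)


# hydropathy on [0, 1] (normalized Kyte-Doolittle), duplicated here only for
# generating synthetic ensemble features; the analysis layer owns its own copy
from .idr_analysis import KYTE_DOOLITTLE_01 as _KD01  # noqa: E402


def simulate_ortholog_proteins(
    config: SimProteomeConfig, rule: ConsensusRule | None = None
) -> SimulatedProteome:
    """Generate MSAs, disorder calls, method call tables and ground truth."""
    rule = rule or ConsensusRule()
    all20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    species = [f"sp{i:02d}" for i in range(config.n_species)]
    msas: dict = {}
    disorder_rows = []
    call_rows = []
    ensemble_rows = []
    truth_sites: dict = {}
    truth_negative: dict = {}
    truth_segments: dict = {}

    for p_idx, (length, segments) in enumerate(
        zip(config.protein_lengths, config.idr_segments)
    ):
        protein = f"prot_{p_idx:04d}"
        rng = np.random.default_rng([int(config.seed), 1000 + p_idx])
        mask = _idr_mask(length, segments)

        # reference sequence with disorder-biased composition inside segments
        ref = np.where(
            mask,
            rng.choice(_DISORDER_AA, size=length),
            rng.choice(_ORDER_AA, size=length),
        )

        # planted positively selected sites: rate * rho inside IDRs
        rho = config.planted_site_enrichment
        p_site = np.where(mask, min(1.0, config.site_rate * rho), config.site_rate)
        pos_sites = np.flatnonzero(rng.random(length) < p_site) + 1  # 1-based
        neg_candidates = np.setdiff1d(np.arange(1, length + 1), pos_sites)
        neg_draw = rng.random(neg_candidates.size) < config.negative_site_rate
        neg_sites = neg_candidates[neg_draw]

        # ortholog sequences: elevated divergence at positively selected sites
        sub_rate = np.full(length, config.divergence)
        sub_rate[pos_sites - 1] = config.selected_divergence
        rows = [(config.reference_species, "".join(ref))]
        seqs = {config.reference_species: ref}
        for sp in species:
            if sp == config.reference_species:
                continue
            seq = ref.copy()
            hit = rng.random(length) < sub_rate
            n_hit = int(hit.sum())
            if n_hit:
                pool = np.where(mask[hit], 0, 1)
                repl = np.where(
                    pool == 0,
                    rng.choice(_DISORDER_AA, size=n_hit),
                    rng.choice(_ORDER_AA, size=n_hit),
                )
                same = repl == seq[hit]
                while same.any():  # substitution must change the residue
                    repl[same] = rng.choice(all20, size=int(same.sum()))
                    same = repl == seq[hit]
                seq[hit] = repl
            rows.append((sp, "".join(seq)))
            seqs[sp] = seq
        msas[protein] = rows

        # per-species noisy disorder calls
        for sp in species:
            p_dis = np.where(mask, 0.0, config.disorder_background).astype(float)
            for a, b, bias in segments:
                p_dis[a - 1 : b] = bias
            called = rng.random(length) < p_dis
            for residue in np.flatnonzero(called) + 1:
                disorder_rows.append((protein, sp, int(residue), 1))

        # per-method call tables (alignment columns == residues: gap-free MSA)
        sens, spec = config.method_sensitivity, config.method_specificity
        non_sites = np.setdiff1d(np.arange(1, length + 1), pos_sites)
        for method in POSITIVE_METHODS:
            detected = pos_sites[rng.random(pos_sites.size) < sens]
            false = non_sites[rng.random(non_sites.size) < 1.0 - spec]
            for col_arr in (detected, false):
                for col in col_arr:
                    if method in ("BEB", "FUBAR"):
                        cutoff = rule.beb_min if method == "BEB" else rule.fubar_min
                        score = cutoff + (1.0 - cutoff) * rng.random()
                    else:
                        cutoff = rule.meme_max_p if method == "MEME" else rule.fel_max_p
                        score = cutoff * rng.random()
                    call_rows.append((protein, method, int(col), float(score), "positive"))
        non_neg = np.setdiff1d(np.arange(1, length + 1), neg_sites)
        slac_detected = neg_sites[rng.random(neg_sites.size) < sens]
        slac_false = non_neg[rng.random(non_neg.size) < 1.0 - spec]
        for col_arr in (slac_detected, slac_false):
            for col in col_arr:
                call_rows.append(
                    (protein, "SLAC", int(col), float(rule.slac_max_p * rng.random()), "negative")
                )

        # synthetic ensemble features: noisy decreasing functions of SHD
        for a, b, _bias in segments:
            for sp in species:
                lam = np.array([_KD01[c] for c in seqs[sp][a - 1 : b]])
                shd_val = _shd_quick(lam)
                ensemble_rows.append(
                    (
                        protein,
                        sp,
                        int(a),
                        int(b),
                        float(3.3 - 0.25 * shd_val + rng.normal(0.0, 0.05)),
                        float(0.62 - 0.03 * shd_val + rng.normal(0.0, 0.01)),
                    )
                )

        truth_sites[protein] = [int(x) for x in pos_sites]
        truth_negative[protein] = [int(x) for x in neg_sites]
        truth_segments[protein] = [[int(a), int(b)] for a, b, _bias in segments]

    idr_total = sum(
        sum(b - a + 1 for a, b, _ in segs) for segs in config.idr_segments
    )
    total = sum(config.protein_lengths)
    truth = {
        "true_positive_sites": truth_sites,
        "true_negative_sites": truth_negative,
        "idr_segments": truth_segments,
        "idr_length_total": int(idr_total),
        "analyzed_length_total": int(total),
        "reference_species": config.reference_species,
    }
    return SimulatedProteome(
        config=config,
        msas=msas,
        disorder=pd.DataFrame(
            disorder_rows, columns=["protein", "species", "residue", "disordered"]
        ),
        calls=pd.DataFrame(call_rows, columns=["protein"] + CALLS_COLUMNS),
        ensemble=pd.DataFrame(
            ensemble_rows,
            columns=["protein", "species", "idr_start", "idr_end", "sconf_per_n", "nu"],
        ),
        truth=truth,
    )


@dataclass(frozen=True)
class SiteCounts:
    """Planted-site tallies for one simulated dataset (enrichment inputs)."""

    m_total: int
    k_in_idr: int
    idr_length_total: int
    analyzed_length_total: int


def sample_site_counts(config: SimProteomeConfig, rng: np.random.Generator) -> SiteCounts:
    """Draw planted-site counts only (no sequences) under ``config``.

    Uses the same per-residue Bernoulli placement law as
    :func:`simulate_ortholog_proteins`, aggregated into two binomials.  This
    is the fast path for calibration loops over many simulated datasets.
    """
    idr_total = sum(sum(b - a + 1 for a, b, _ in segs) for segs in config.idr_segments)
    total = sum(config.protein_lengths)
    out_total = total - idr_total
    p_in = min(1.0, config.site_rate * config.planted_site_enrichment)
    k_in = int(rng.binomial(idr_total, p_in))
    k_out = int(rng.binomial(out_total, config.site_rate))
    return SiteCounts(
        m_total=k_in + k_out,
        k_in_idr=k_in,
        idr_length_total=int(idr_total),
        analyzed_length_total=int(total),
    )
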