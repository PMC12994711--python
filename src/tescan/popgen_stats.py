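"""Windowed site-frequency-spectrum statistics from polarized variants.

All estimators operate on the *unfolded* site frequency spectrum: every
segregating site in a window carries a derived-allele count ``x`` with
``0 < x < n``, where ``n`` is the haploid sample size and ancestral/derived
orientation comes from an ``AA`` (ancestral allele) annotation.

Implemented estimators (per window, summed over sites -- not per bp):

* nucleotide diversity  ``pi = sum 2 x (n - x) / (n (n - 1))``
  (mean pairwise Hamming distance);
* Watterson's           ``theta_W = S / a1``,  ``a1 = sum_{i<n} 1/i``;
* Fay & Wu's            ``theta_H = sum 2 x^2 / (n (n - 1))``;
* Tajima's D, the variance-normalized ``pi - theta_W``;
* Fay & Wu's H, the unnormalized ``pi - theta_H``.

Windows with ``S = 0`` have undefined D and H (returned as NaN and written
as ``NA``), never 0: an invariant window carries no rank information and
would otherwise spuriously rank as non-extreme in the genome scan.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PolarizedWindow",
    "SummaryStatConstants",
    "WindowStats",
    "pi",
    "theta_w",
    "theta_h",
    "tajimas_d",
    "fay_wu_h",
    "window_stats",
    "tile_windows",
    "windows_from_vcf",
    "stats_table",
    "write_stats_tsv",
    "read_stats_tsv",
]

STATS_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n",
    "S",
    "pi",
    "theta_w",
    "theta_h",
    "tajimas_d",
    "fay_wu_h",
]


@dataclass(frozen=True)
class PolarizedWindow:
    """Derived-allele counts for the segregating sites of one genomic window.

    Coordinates are 0-based, half-open.  ``derived_counts`` holds one integer
    per segregating site, each strictly between 0 and ``n``.
    """

    chrom: str
    start: int
    end: int
    n: int
    derived_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end must exceed start ({self.start}, {self.end})")
        if self.n < 2:
            raise ValueError(f"sample size n must be >= 2, got {self.n}")
        counts = tuple(int(x) for x in self.derived_counts)
        object.__setattr__(self, "derived_counts", counts)
        for x in counts:
            if not 0 < x < self.n:
                raise ValueError(
                    f"derived count {x} outside (0, {self.n}); "
                    "monomorphic sites must be dropped before construction"
                )

    @property
    def S(self) -> int:
        return len(self.derived_counts)

    @property
    def length(self) -> int:
        return self.end - self.start


@lru_cache(maxsize=None)
def _constants(n: int) -> "SummaryStatConstants":
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return SummaryStatConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


@dataclass(frozen=True)
class SummaryStatConstants:
    """Tajima (1989) normalization coefficients; functions of ``n`` only."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_sample_size(cls, n: int) -> "SummaryStatConstants":
        if n < 2:
            raise ValueError(f"sample size n must be >= 2, got {n}")
        return _constants(int(n))


def pi(window: PolarizedWindow) -> float:
    """Nucleotide diversity: mean pairwise difference, summed over sites."""
    n = window.n
    x = np.asarray(window.derived_counts, dtype=float)
    return float(np.sum(2.0 * x * (n - x)) / (n * (n - 1)))


def theta_w(S: int, n: int) -> float:
    """Watterson's estimator ``S / a1(n)``."""
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    if S < 0:
        raise ValueError(f"segregating-site count must be >= 0, got {S}")
    return S / SummaryStatConstants.for_sample_size(n).a1


def theta_h(window: PolarizedWindow) -> float:
    """Fay & Wu's estimator weighting high-frequency derived alleles."""
    n = window.n
    x = np.asarray(window.derived_counts, dtype=float)
    return float(np.sum(2.0 * x**2) / (n * (n - 1)))


def tajimas_d(window: PolarizedWindow) -> float:
    """Tajima's D; NaN when ``S = 0`` or the variance term vanishes."""
    S = window.S
    if S == 0:
        return math.nan
    c = SummaryStatConstants.for_sample_size(window.n)
    denom_sq = c.e1 * S + c.e2 * S * (S - 1)
    if denom_sq <= 0.0:
        return math.nan
    return (pi(window) - theta_w(S, window.n)) / math.sqrt(denom_sq)


def fay_wu_h(window: PolarizedWindow) -> float:
    """Unnormalized Fay & Wu's H = pi - theta_H; NaN when ``S = 0``."""
    if window.S == 0:
        return math.nan
    return pi(window) - theta_h(window)


@dataclass(frozen=True)
class WindowStats:
    """All summary statistics for one window (sums over sites + per-bp)."""

    chrom: str
    start: int
    end: int
    n: int
    S: int
    pi: float
    theta_w: float
    theta_h: float
    tajimas_d: float
    fay_wu_h: float

    @property
    def pi_per_bp(self) -> float:
        return self.pi / (self.end - self.start)

    @property
    def theta_w_per_bp(self) -> float:
        return self.theta_w / (self.end - self.start)

    @property
    def theta_h_per_bp(self) -> float:
        return self.theta_h / (self.end - self.start)


def window_stats(window: PolarizedWindow) -> WindowStats:
    return WindowStats(
        chrom=window.chrom,
        start=window.start,
        end=window.end,
        n=window.n,
        S=window.S,
        pi=pi(window),
        theta_w=theta_w(window.S, window.n),
        theta_h=theta_h(window),
        tajimas_d=tajimas_d(window),
        fay_wu_h=fay_wu_h(window),
    )


def tile_windows(length: int, size: int = 50_000, step: int = 10_000) -> Iterator[tuple[int, int]]:
    """Yield 0-based half-open sliding windows over ``[0, length)``.

    The final window is truncated at the chromosome end rather than dropped;
    tiling stops once a window reaches the end, so a 100-kb chromosome at
    50 kb / 10 kb yields starts 0, 10k, ..., 50k (six windows).
    """
    if length <= 0:
        raise ValueError(f"chromosome length must be positive, got {length}")
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    start = 0
    while True:
        end = min(start + size, length)
        yield (start, end)
        if end >= length:
            return
        start += step


def windows_from_vcf(
    vcf_path: str | Path,
    *,
    size: int = 50_000,
    step: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[PolarizedWindow], Counter]:
    """Read a polarized VCF into sliding :class:`PolarizedWindow` objects.

    The VCF must carry the ancestral allele in ``INFO/AA``.  Sites are
    polarized case-insensitively against REF/ALT; sites whose AA matches
    neither, multi-allelic sites, sites missing AA or with missing genotypes,
    and sites monomorphic after polarization are skipped and tallied in the
    returned counter.  Chromosome lengths default to the header contigs.
    """
    from cyvcf2 import VCF  # heavy import kept local to the I/O edge

    tally: Counter = Counter()
    vcf = VCF(str(vcf_path))
    if chrom_lengths is None:
        chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
        if not chrom_lengths:
            raise ValueError(f"{vcf_path}: no contig lengths in header and none supplied")

    positions: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    counts: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    n_alleles: int | None = None

    for v in vcf:
        if v.CHROM not in chrom_lengths:
            tally["unknown_chrom"] += 1
            continue
        if len(v.ALT) != 1:
            tally["multiallelic"] += 1
            continue
        aa = v.INFO.get("AA")
        if aa is None:
            tally["missing_aa"] += 1
            continue
        gts = np.asarray(v.genotypes, dtype=int)[:, :-1]
        if (gts < 0).any():
            tally["missing_genotype"] += 1
            continue
        n_here = gts.size
        if n_alleles is None:
            n_alleles = n_here
        elif n_here != n_alleles:
            raise ValueError(f"{vcf_path}: inconsistent ploidy at {v.CHROM}:{v.POS}")
        alt_count = int((gts == 1).sum())
        aa_u = str(aa).upper()
        if aa_u == v.REF.upper():
            derived = alt_count
        elif aa_u == v.ALT[0].upper():
            derived = n_here - alt_count
        else:
            tally["aa_mismatch"] += 1
            continue
        if derived == 0 or derived == n_here:
            tally["monomorphic"] += 1
            continue
        positions[v.CHROM].append(v.POS - 1)  # VCF POS is 1-based
        counts[v.CHROM].append(derived)
        tally["used"] += 1

    if n_alleles is None:
        # empty VCF: assume diploid samples so windows can still be emitted
        n_alleles = 2 * len(vcf.samples)
        tally["empty_vcf"] += 1
    if n_alleles < 2:
        raise ValueError(f"{vcf_path}: fewer than 2 haplotypes")

    windows: list[PolarizedWindow] = []
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(positions[chrom], dtype=int)
        cnt = np.asarray(counts[chrom], dtype=int)
        order = np.argsort(pos, kind="stable")
        pos, cnt = pos[order], cnt[order]
        for start, end in tile_windows(length, size=size, step=step):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            windows.append(
                PolarizedWindow(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n=n_alleles,
                    derived_counts=tuple(int(x) for x in cnt[lo:hi]),
                )
            )
    return windows, tally


def stats_table(windows: Iterable[PolarizedWindow]) -> pd.DataFrame:
    """Summary statistics for a sequence of windows as a tidy table."""
    rows = []
    for w in windows:
        s = window_stats(w)
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n": s.n,
                "S": s.S,
                "pi": s.pi,
                "theta_w": s.theta_w,
                "theta_h": s.theta_h,
                "tajimas_d": s.tajimas_d,
                "fay_wu_h": s.fay_wu_h,
            }
        )
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def write_stats_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_stats_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
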