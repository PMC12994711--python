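"""Consensus calling of per-site selection signals on reference coordinates.

Site-level positive selection evidence comes from four methods -- codeml's
Bayes Empirical Bayes (BEB), FUBAR, MEME and FEL -- each consumed as a
normalized call table (method, alignment column, score, direction).  A column
is a consensus positive-selection target when at least ``min_methods``
methods pass their own threshold: posterior probability >= 0.90 for BEB and
FUBAR, p-value < 0.1 for MEME and FEL.  SLAC identifies purifying selection
and never contributes to the positive consensus.

Columns live on the multiple sequence alignment; :func:`map_column_to_reference`
projects them onto reference-protein residue numbers by skipping reference
gap columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "POSITIVE_METHODS",
    "ALL_METHODS",
    "CALLS_COLUMNS",
    "ConsensusRule",
    "read_msa_fasta",
    "map_column_to_reference",
    "reference_to_column",
    "call_consensus_sites",
    "consensus_table",
    "negative_sites",
    "selected_fraction",
    "fraction_negative_per_idr",
    "read_calls_tsv",
    "calls_from_hyphy_json",
    "calls_from_codeml_beb",
]

POSITIVE_METHODS = ("BEB", "FUBAR", "MEME", "FEL")
ALL_METHODS = POSITIVE_METHODS + ("SLAC",)
CALLS_COLUMNS = ["method", "column", "score", "direction"]


@dataclass(frozen=True)
class ConsensusRule:
    """Per-method thresholds and the minimum concurring-method count.

    BEB/FUBAR pass at score >= cutoff (posterior probabilities); MEME/FEL
    pass at p-value strictly below the cutoff; SLAC (negative selection)
    passes at p-value <= ``slac_max_p`` (boundary inclusive).
    """

    beb_min: float = 0.90
    fubar_min: float = 0.90
    meme_max_p: float = 0.1
    fel_max_p: float = 0.1
    slac_max_p: float = 0.1
    min_methods: int = 2

    def __post_init__(self) -> None:
        for t in (self.beb_min, self.fubar_min, self.meme_max_p, self.fel_max_p, self.slac_max_p):
            if not 0.0 < t < 1.0:
                raise ValueError(f"threshold {t} outside (0, 1)")
        if self.min_methods < 1:
            raise ValueError("min_methods must be >= 1")

    def passes(self, method: str, score: float) -> bool:
        if method == "BEB":
            return score >= self.beb_min
        if method == "FUBAR":
            return score >= self.fubar_min
        if method == "MEME":
            return score < self.meme_max_p
        if method == "FEL":
            return score < self.fel_max_p
        if method == "SLAC":
            return score <= self.slac_max_p
        raise KeyError(f"unknown method {method!r}")


def read_msa_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Aligned FASTA as (id, sequence) pairs, preserving file order."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no sequences")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError(f"{path}: sequences are not aligned (lengths {sorted(lengths)})")
    return records


def _reference_sequence(msa: Sequence[tuple[str, str]], reference_id: str) -> str:
    for name, seq in msa:
        if name == reference_id:
            return seq
    raise KeyError(f"reference {reference_id!r} not present in alignment")


def map_column_to_reference(
    msa: Sequence[tuple[str, str]], reference_id: str
) -> dict[int, int]:
    """1-based alignment column -> 1-based reference residue (gaps unmapped)."""
    seq = _reference_sequence(msa, reference_id)
    mapping: dict[int, int] = {}
    residue = 0
    for col, ch in enumerate(seq, start=1):
        if ch != "-":
            residue += 1
            mapping[col] = residue
    return mapping


def reference_to_column(
    msa: Sequence[tuple[str, str]], reference_id: str
) -> dict[int, int]:
    """Inverse of :func:`map_column_to_reference` (a bijection on residues)."""
    return {res: col for col, res in map_column_to_reference(msa, reference_id).items()}


def _validated_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALLS_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table lacks columns {missing}")
    unknown = set(calls["method"].unique()) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown method name(s) {sorted(unknown)}")
    if calls.duplicated(subset=["method", "column"]).any():
        raise ValueError("call table has duplicate (method, column) entries")
    bad = calls[(calls["score"] < 0) | (calls["score"] > 1)]
    if len(bad):
        raise ValueError("scores must lie in [0, 1]")
    if (calls["column"] < 1).any():
        raise ValueError("alignment columns are 1-based")
    return calls


def consensus_table(calls: pd.DataFrame, rule: ConsensusRule | None = None) -> pd.DataFrame:
    """Per-column positive-method votes and the consensus flag."""
    rule = rule or ConsensusRule()
    calls = _validated_calls(calls)
    votes = calls[
        calls["method"].isin(POSITIVE_METHODS)
        & (calls["direction"] == "positive")
        & calls.apply(lambda r: rule.passes(r["method"], r["score"]), axis=1)
    ]
    if votes.empty:
        return pd.DataFrame(columns=["column", "n_methods", "methods", "consensus"])
    grouped = (
        votes.groupby("column")["method"]
        .agg(["nunique", lambda m: ",".join(sorted(m))])
        .reset_index()
    )
    grouped.columns = ["column", "n_methods", "methods"]
    grouped["consensus"] = grouped["n_methods"] >= rule.min_methods
    return grouped.sort_values("column").reset_index(drop=True)


def call_consensus_sites(calls: pd.DataFrame, rule: ConsensusRule | None = None) -> list[int]:
    """Alignment columns called positively selected by >= ``min_methods``."""
    table = consensus_table(calls, rule)
    if table.empty:
        return []
    return [int(c) for c in table.loc[table["consensus"], "column"]]


def negative_sites(calls: pd.DataFrame, rule: ConsensusRule | None = None) -> list[int]:
    """Columns under purifying selection per SLAC (p <= cutoff, inclusive)."""
    rule = rule or ConsensusRule()
    calls = _validated_calls(calls)
    hits = calls[
        (calls["method"] == "SLAC")
        & (calls["direction"] == "negative")
        & (calls["score"] <= rule.slac_max_p)
    ]
    return sorted(int(c) for c in hits["column"].unique())


def warn_on_overlap(positive: Iterable[int], negative: Iterable[int], protein: str = "") -> set:
    """Positive/negative sets may overlap; report, never enforce disjointness."""
    overlap = set(positive) & set(negative)
    if overlap:
        warnings.warn(
            f"{protein or 'alignment'}: {len(overlap)} column(s) called both "
            f"positively and negatively selected",
            stacklevel=2,
        )
    return overlap


def selected_fraction(n_sites: int, protein_length: int) -> float:
    """Fraction of residues under positive selection for one protein."""
    if protein_length <= 0:
        raise ValueError(f"protein length must be positive, got {protein_length}")
    if not 0 <= n_sites <= protein_length:
        raise ValueError(f"site count {n_sites} outside [0, {protein_length}]")
    return n_sites / protein_length


def fraction_negative_per_idr(
    negative_residues: Iterable[int],
    idrs: Iterable[tuple[int, int]],
    protein_length: int | None = None,
) -> list[float]:
    """Per-IDR fraction of residues under purifying selection.

    IDR intervals are 1-based inclusive on the reference protein; boundary
    residues count as inside.  The denominator is the IDR residue length.
    """
    residues = sorted(set(int(r) for r in negative_residues))
    out = []
    for start, end in idrs:
        if end < start or start < 1:
            raise ValueError(f"invalid IDR interval ({start}, {end})")
        if protein_length is not None and end > protein_length:
            raise ValueError(f"IDR interval ({start}, {end}) beyond protein length {protein_length}")
        inside = sum(1 for r in residues if start <= r <= end)
        out.append(inside / (end - start + 1))
    return out


# --------------------------------------------------------------------------
# I/O-edge adapters for third-party result formats
# --------------------------------------------------------------------------


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t")
    return _validated_calls(calls[[c for c in calls.columns]])


_HYPHY_SCORE_HEADERS = {
    "FUBAR": ("Prob[alpha<beta]",),
    "MEME": ("p-value",),
    "FEL": ("p-value",),
    "SLAC": ("P [dN/dS > 1]", "P [dN/dS < 1]"),
}


def calls_from_hyphy_json(path: str | Path, method: str) -> pd.DataFrame:
    """Normalize a HyPhy results JSON (``MLE`` block) into the call schema.

    For SLAC both tail probabilities are read; the purifying tail is emitted
    with direction ``negative`` and the diversifying tail is ignored (SLAC
    is used here only for negative selection).
    """
    import json

    if method not in ("FUBAR", "MEME", "FEL", "SLAC"):
        raise ValueError(f"no HyPhy adapter for method {method!r}")
    with open(path) as fh:
        data = json.load(fh)
    headers = [h[0] for h in data["MLE"]["headers"]]
    rows = []
    for partition in data["MLE"]["content"].values():
        rows.extend(partition)
    wanted = _HYPHY_SCORE_HEADERS[method]
    out = []
    for col, row in enumerate(rows, start=1):
        if method == "SLAC":
            idx = headers.index("P [dN/dS < 1]")
            out.append((method, col, float(row[idx]), "negative"))
        else:
            idx = headers.index(wanted[0])
            out.append((method, col, float(row[idx]), "positive"))
    return pd.DataFrame(out, columns=CALLS_COLUMNS)


def calls_from_codeml_beb(text: str) -> pd.DataFrame:
    """Parse codeml's BEB site block (``site  residue  probability``) lines."""
    import re

    pattern = re.compile(r"^\s*(\d+)\s+([A-Z*-])\s+([01]\.\d+)\**\s*$", re.MULTILINE)
    rows = [
        ("BEB", int(m.group(1)), float(m.group(3)), "positive")
        for m in pattern.finditer(text)
    ]
    return pd.DataFrame(rows, columns=CALLS_COLUMNS)
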