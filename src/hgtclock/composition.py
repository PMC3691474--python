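"""Codon-position G+C content and dinucleotide genome-signature statistics.

GC1/GC2/GC3 are the G+C fractions at first/second/third codon positions.
GC3 is the least selectively constrained and tracks directional mutation
pressure most closely, which is why downstream modules treat it as the
independent variable.

The dinucleotide signature uses Karlin's relative abundance
rho*_XY = f_XY / (f_X f_Y) computed on the sequence concatenated with its
reverse complement (symmetrized counting), and the delta* distance is the
mean absolute difference of the 16 rho* values between two sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seq_io import CodonSequence, reverse_complement

__all__ = [
    "GCProfile",
    "DinucleotideProfile",
    "codon_position_gc",
    "genome_gc_stats",
    "dinucleotide_profile",
    "delta_star",
    "profiles_to_tsv",
]


DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


@dataclass(frozen=True)
class GCProfile:
    """G+C fractions per codon position for one sequence or a pool."""

    gc1: float
    gc2: float
    gc3: float
    n_codons: int
    n_excluded_positions: int = 0

    @property
    def gc_total(self) -> float:
        """Mean of the three positional fractions.

        Equals the overall unambiguous G+C fraction exactly when no
        positions were excluded; with exclusions it remains the
        position-balanced summary used throughout.
        """
        return (self.gc1 + self.gc2 + self.gc3) / 3.0

    def as_array(self) -> np.ndarray:
        return np.array([self.gc1, self.gc2, self.gc3], dtype=float)


def codon_position_gc(cs: CodonSequence | Iterable[CodonSequence]) -> GCProfile:
    """Per-position G+C of one CodonSequence or a pooled collection.

    Pooling is by concatenation (total counts), not a mean of per-gene
    fractions. Ambiguous bases are excluded from both numerator and
    denominator of their position.
    """
    if isinstance(cs, CodonSequence):
        seqs: list[CodonSequence] = [cs]
    else:
        seqs = list(cs)
        if not seqs:
            raise ValueError("no codon sequences given")
    concat = "".join(s.nucleotides for s in seqs)
    n_codons = len(concat) // 3
    arr = np.frombuffer(concat.encode(), dtype="S1").reshape(n_codons, 3)
    is_gc = (arr == b"G") | (arr == b"C")
    is_at = (arr == b"A") | (arr == b"T")
    gc = is_gc.sum(axis=0)
    valid = gc + is_at.sum(axis=0)
    if valid.sum() == 0:
        raise ValueError("all positions ambiguous; no G+C content defined")
    n_excluded = int(3 * n_codons - valid.sum())
    # A position with zero unambiguous bases yields 0/0; report 0 for that
    # position only if at least one position is informative.
    frac = np.divide(gc, valid, out=np.zeros(3), where=valid > 0)
    return GCProfile(
        gc1=float(frac[0]),
        gc2=float(frac[1]),
        gc3=float(frac[2]),
        n_codons=n_codons,
        n_excluded_positions=n_excluded,
    )


def genome_gc_stats(genes: Sequence[GCProfile]) -> tuple[float, float]:
    """Mean and sample SD (n-1) of per-gene total G+C, in percent."""
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for genome G+C statistics")
    vals = np.array([g.gc_total for g in genes], dtype=float) * 100.0
    return float(vals.mean()), float(vals.std(ddof=1))


@dataclass(frozen=True)
class DinucleotideProfile:
    """Karlin relative abundances rho*_XY from symmetrized counting."""

    rho_star: dict[str, float]
    length_used: int

    def __post_init__(self) -> None:
        missing = set(DINUCLEOTIDES) - set(self.rho_star)
        if missing:
            raise ValueError(f"profile missing dinucleotides {sorted(missing)}")

    @property
    def degenerate(self) -> bool:
        return any(not np.isfinite(v) for v in self.rho_star.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_star[d] for d in DINUCLEOTIDES], dtype=float)


def dinucleotide_profile(seq: str) -> DinucleotideProfile:
    """rho*_XY on ``seq`` + its reverse complement, overlapping windows.

    Symmetrization makes the profile strand-invariant. Windows containing
    an ambiguous base are skipped; mononucleotide frequencies come from the
    same symmetrized string.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 nt")
    sym = seq + reverse_complement(seq)
    arr = np.frombuffer(sym.encode(), dtype="S1")
    idx = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        idx[arr == bytes([b])] = i
    valid = idx >= 0
    mono = np.bincount(idx[valid], minlength=4).astype(float)
    if valid.sum() == 0:
        raise ValueError("no unambiguous bases")
    f_mono = mono / mono.sum()
    # Overlapping dinucleotides within each strand copy (no window spanning
    # the concatenation seam).
    half = len(seq)
    pair_counts = np.zeros((4, 4), dtype=float)
    for a, b in ((idx[:half], valid[:half]), (idx[half:], valid[half:])):
        ok = b[:-1] & b[1:]
        if ok.any():
            np.add.at(pair_counts, (a[:-1][ok], a[1:][ok]), 1.0)
    n_pairs = pair_counts.sum()
    if n_pairs < 2:
        raise ValueError("fewer than 2 unambiguous adjacent pairs")
    f_pair = pair_counts / n_pairs
    rho = {}
    for i, x in enumerate("ACGT"):
        for j, y in enumerate("ACGT"):
            denom = f_mono[i] * f_mono[j]
            rho[x + y] = float(f_pair[i, j] / denom) if denom > 0 else float("nan")
    return DinucleotideProfile(rho_star=rho, length_used=int(valid[:half].sum()))


def delta_star(a: DinucleotideProfile, b: DinucleotideProfile) -> float:
    """Mean absolute rho* difference over the 16 dinucleotides."""
    if a.degenerate or b.degenerate:
        raise ValueError("degenerate dinucleotide profile (missing base class)")
    return float(np.abs(a.as_array() - b.as_array()).mean())


def profiles_to_tsv(
    profiles: Sequence[tuple[str, GCProfile]], path: str | Path
) -> None:
    """Write per-gene profiles as TSV (fractions at 4 decimals)."""
    df = pd.DataFrame(
        [
            {
                "locus_tag": tag,
                "n_codons": p.n_codons,
                "gc1": round(p.gc1, 4),
                "gc2": round(p.gc2, 4),
                "gc3": round(p.gc3, 4),
                "gc_total": round(p.gc_total, 4),
            }
            for tag, p in profiles
        ],
        columns=["locus_tag", "n_codons", "gc1", "gc2", "gc3", "gc_total"],
    )
    df.to_csv(path, sep="\t", index=False)
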