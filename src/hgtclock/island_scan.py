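"""Genomic-island detection from G+C deviation and dinucleotide bias.

A genomic island is a contiguous run of genes whose composition departs
from the genome background — the signature of relatively recent horizontal
acquisition. Two evidence channels are combined (OR):

* per-gene total G+C more than ``gc_sd_threshold`` scale units from the
  genome background (the 2-SD rule);
* dinucleotide signature distance delta* of a sliding window of
  consecutive CDS against the whole-genome profile exceeding the window
  background by ``bias_sd_threshold`` scale units.

Genes flagged by either channel are "hot"; islands are maximal runs of
hot genes tolerating short cold gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .composition import (
    DinucleotideProfile,
    GCProfile,
    delta_star,
    dinucleotide_profile,
    genome_gc_stats,
)
from .seq_io import CdsFeature

__all__ = [
    "IslandConfig",
    "IslandCall",
    "flag_gc_outliers",
    "flag_bias_windows",
    "call_islands",
    "scan_genome",
    "islands_to_bed",
    "islands_to_tsv",
]


@dataclass(frozen=True)
class IslandConfig:
    """Detection thresholds.

    ``robust`` selects median/MAD background statistics for both outlier
    channels (the default): islands large enough to matter inflate a plain
    mean/SD estimated from all genes or windows and thereby mask
    themselves. With ``robust=False`` both channels use the classical
    mean/SD background. ``bias_sd_threshold`` defaults to 4 because the
    window delta* null distribution is right-skewed and every flagged
    window spans ``bias_window`` genes — more than ``min_run`` — so the
    per-window false-positive rate must be held near zero for island calls
    to stay clean on unremarkable genomes.
    """

    gc_sd_threshold: float = 2.0
    bias_window: int = 8  # consecutive CDS per delta* window
    bias_sd_threshold: float = 4.0
    min_run: int = 6  # minimum hot CDS per island
    max_gap: int = 1  # tolerated consecutive cold CDS inside a run
    robust: bool = True

    def __post_init__(self) -> None:
        if min(self.gc_sd_threshold, self.bias_sd_threshold) <= 0:
            raise ValueError("SD thresholds must be positive")
        if self.bias_window < 1 or self.max_gap < 0:
            raise ValueError("bad window/gap configuration")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")


@dataclass(frozen=True)
class IslandCall:
    contig_id: str
    start: int  # 1-based inclusive, span of first..last hot gene
    end: int
    locus_tags: tuple[str, ...]
    mean_gc: float  # percent
    flags: frozenset[str]  # which channels fired: {"gc"}, {"bias"}, or both

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("island start must precede end")
        if not self.locus_tags:
            raise ValueError("island with no locus tags")
        if not 0.0 <= self.mean_gc <= 100.0:
            raise ValueError("mean_gc outside [0,100]")


def _background(vals: np.ndarray, robust: bool) -> tuple[float, float]:
    """Location/scale of a null background, optionally masking-resistant.

    The robust pair (median, 1.4826 * MAD) matches (mean, SD) on clean
    Gaussian data but is not dragged by the very outliers being sought.
    """
    if robust:
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        return med, 1.4826 * mad
    return float(vals.mean()), float(vals.std(ddof=1))


def flag_gc_outliers(
    genes: Sequence[tuple[CdsFeature, GCProfile]],
    cfg: IslandConfig = IslandConfig(),
) -> np.ndarray:
    """Per-gene boolean: |gc_total - center| > threshold * scale (percent).

    With the default robust background this is the 2-SD rule with the
    genome mean/SD replaced by median/scaled-MAD so a sizeable island
    cannot inflate the threshold that is supposed to catch it.
    """
    if len(genes) < 10:
        raise ValueError("need >= 10 genes for stable genome G+C statistics")
    vals = np.array([p.gc_total for _, p in genes]) * 100.0
    center, scale = _background(vals, cfg.robust)
    return np.abs(vals - center) > cfg.gc_sd_threshold * scale


def window_deltas(
    seqs: Sequence[str], genome_profile: DinucleotideProfile, window: int
) -> np.ndarray:
    """delta* of each sliding window of ``window`` consecutive CDS
    (concatenated) against the genome profile; length n - window + 1."""
    n = len(seqs)
    if n < window:
        raise ValueError(f"fewer genes ({n}) than bias_window ({window})")
    out = np.empty(n - window + 1)
    for i in range(n - window + 1):
        win_prof = dinucleotide_profile("".join(seqs[i : i + window]))
        out[i] = delta_star(win_prof, genome_profile)
    return out


def flag_bias_windows(
    genes: Sequence[tuple[CdsFeature, str]],
    genome_profile: DinucleotideProfile,
    cfg: IslandConfig = IslandConfig(),
) -> np.ndarray:
    """Per-gene boolean from sliding-window delta* against the genome.

    Windows of ``bias_window`` consecutive CDS (concatenated) are scored by
    delta* against the genome profile; a window is flagged when its delta*
    exceeds the across-window background center by ``bias_sd_threshold``
    scale units, and a gene is flagged when any window containing it is
    flagged. Genes must be in genomic order.
    """
    n = len(genes)
    w = cfg.bias_window
    seqs = [s for _, s in genes]
    deltas = window_deltas(seqs, genome_profile, w)
    center, scale = _background(deltas, cfg.robust)
    win_flag = deltas > center + cfg.bias_sd_threshold * scale
    gene_flag = np.zeros(n, dtype=bool)
    for i in np.nonzero(win_flag)[0]:
        gene_flag[i : i + w] = True
    return gene_flag


def call_islands(
    gc_flags: np.ndarray,
    bias_flags: np.ndarray,
    genes: Sequence[tuple[CdsFeature, GCProfile]],
    cfg: IslandConfig = IslandConfig(),
) -> list[IslandCall]:
    """Merge hot genes (gc OR bias) into island calls.

    Islands are maximal runs of hot genes allowing up to ``max_gap``
    consecutive cold genes inside, and must contain at least ``min_run``
    hot genes. Island coordinates span the first to last *hot* gene.
    """
    gc_flags = np.asarray(gc_flags, dtype=bool)
    bias_flags = np.asarray(bias_flags, dtype=bool)
    if not (len(gc_flags) == len(bias_flags) == len(genes)):
        raise ValueError("flag vectors must align with the gene list")
    hot = gc_flags | bias_flags
    calls: list[IslandCall] = []
    i = 0
    n = len(genes)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        # extend run: absorb cold gaps of length <= max_gap followed by heat
        j = i
        last_hot = i
        while j + 1 < n:
            if hot[j + 1]:
                j += 1
                last_hot = j
                continue
            gap_end = j + 1
            while gap_end < n and not hot[gap_end]:
                gap_end += 1
            if gap_end < n and (gap_end - (j + 1)) <= cfg.max_gap:
                j = gap_end
                last_hot = j
            else:
                break
        members = list(range(i, last_hot + 1))
        hot_members = [m for m in members if hot[m]]
        if len(hot_members) >= cfg.min_run:
            first, last = hot_members[0], hot_members[-1]
            span_feats = [genes[m][0] for m in range(first, last + 1)]
            span_profiles = [genes[m][1] for m in range(first, last + 1)]
            flags = set()
            if gc_flags[first : last + 1].any():
                flags.add("gc")
            if bias_flags[first : last + 1].any():
                flags.add("bias")
            calls.append(
                IslandCall(
                    contig_id=span_feats[0].contig_id,
                    start=min(f.start for f in span_feats),
                    end=max(f.end for f in span_feats),
                    locus_tags=tuple(f.locus_tag for f in span_feats),
                    mean_gc=float(
                        np.mean([p.gc_total for p in span_profiles]) * 100.0
                    ),
                    flags=frozenset(flags),
                )
            )
        i = last_hot + 1
    return calls


def scan_genome(
    genes: Sequence[tuple[CdsFeature, GCProfile, str]],
    genome_sequence: str,
    cfg: IslandConfig = IslandConfig(),
) -> list[IslandCall]:
    """Convenience wrapper: both channels plus island calling.

    ``genes`` carries (feature, profile, cds_nucleotides) in genomic order;
    ``genome_sequence`` is the full contig for the background dinucleotide
    profile.
    """
    gc_flags = flag_gc_outliers([(f, p) for f, p, _ in genes], cfg)
    genome_prof = dinucleotide_profile(genome_sequence)
    bias_flags = flag_bias_windows([(f, s) for f, _, s in genes], genome_prof, cfg)
    return call_islands(gc_flags, bias_flags, [(f, p) for f, p, _ in genes], cfg)


def islands_to_bed(calls: Sequence[IslandCall], path: str | Path) -> None:
    """BED output (0-based half-open)."""
    with open(path, "w") as fh:
        for k, c in enumerate(calls, 1):
            fh.write(
                f"{c.contig_id}\t{c.start - 1}\t{c.end}\tisland_{k}\t"
                f"{c.mean_gc:.1f}\t.\n"
            )


def islands_to_tsv(calls: Sequence[IslandCall], path: str | Path) -> None:
    """TSV report (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("contig_id\tstart\tend\tn_genes\tmean_gc\tflags\tlocus_tags\n")
        for c in calls:
            fh.write(
                f"{c.contig_id}\t{c.start}\t{c.end}\t{len(c.locus_tags)}\t"
                f"{c.mean_gc:.1f}\t{','.join(sorted(c.flags))}\t"
                f"{','.join(c.locus_tags)}\n"
            )
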