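"""Pairwise dS/dN estimation and empirical-clock dating of paralogs.

Two estimators are provided for synonymous (dS) and non-synonymous (dN)
substitutions per site between a pair of in-frame coding sequences:

* NG86 — Nei-Gojobori counting with equal weighting of all substitution
  pathways through multi-hit codons, stop-codon-transiting pathways
  excluded with pathway reweighting, stop-adjacent site counts
  renormalized so every codon contributes exactly 3 sites, and the
  Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p).
* GY94 — maximum likelihood under a Goldman-Yang codon substitution model
  with F3x4 codon frequencies, optimizing (t, kappa, omega).

Divergence times follow an empirical molecular clock: 0.91% substitutions
per synonymous site per My and 0.045% per non-synonymous site per My, so
tS = dS / 0.0091 and tN = dN / 0.00045.

Translation uses the bacterial genetic code (table 11).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .seq_io import CodonSequence, translate_codons

__all__ = [
    "ClockRates",
    "CodonAlignment",
    "ParalogPairResult",
    "align_paralogs",
    "ng86_sites",
    "estimate_dnds_ng86",
    "estimate_dnds_gy94",
    "divergence_times",
    "count_substitutions",
    "summarize_cluster_ages",
    "pair_result_from_rates",
    "load_reference_table",
    "SENSE_CODONS",
    "GENETIC_CODE",
]

_TABLE = CodonTable.unambiguous_dna_by_id[11]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if set(c) <= set("ACGT"))
)
_BASES = "ACGT"


@dataclass(frozen=True)
class ClockRates:
    """Empirical per-site substitution rates (per My)."""

    syn_rate: float = 0.0091
    nonsyn_rate: float = 0.00045

    def __post_init__(self) -> None:
        if self.syn_rate <= 0 or self.nonsyn_rate <= 0:
            raise ValueError("clock rates must be positive")


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts for one sense codon.

    At each of the 3 positions the single-nucleotide neighbors are
    classified; changes producing stop codons are excluded and the
    position's contribution renormalized so it always counts as one site
    (hence s + n = 3 exactly).
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = GENETIC_CODE.get(codon)
    if aa is None:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=1)
def _pair_diff_table() -> dict[tuple[str, str], tuple[float, float] | None]:
    """Per ordered sense-codon pair: (syn, nonsyn) differences, pathway-
    averaged; None when every pathway transits a stop codon."""
    table: dict[tuple[str, str], tuple[float, float] | None] = {}
    for c1, c2 in itertools.product(SENSE_CODONS, repeat=2):
        diff = [i for i in range(3) if c1[i] != c2[i]]
        if not diff:
            table[(c1, c2)] = (0.0, 0.0)
            continue
        syn_tot = nsyn_tot = 0.0
        n_paths = 0
        for order in itertools.permutations(diff):
            cur = c1
            syn = nsyn = 0.0
            blocked = False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS:
                    blocked = True
                    break
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    syn += 1
                else:
                    nsyn += 1
                cur = nxt
            if not blocked:
                syn_tot += syn
                nsyn_tot += nsyn
                n_paths += 1
        table[(c1, c2)] = (
            (syn_tot / n_paths, nsyn_tot / n_paths) if n_paths else None
        )
    return table


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """A gap- and ambiguity-free pairwise codon alignment."""

    locus_1: str
    locus_2: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    n_codons_dropped: int
    identity: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned codon lists differ in length")

    @property
    def n_codons_used(self) -> int:
        return len(self.codons_a)


def _check_internal_stops(cs: CodonSequence, protein: str) -> str:
    body = protein[:-1] if protein.endswith("*") else protein
    if "*" in body:
        pos = body.index("*") + 1
        raise ValueError(
            f"{cs.locus_tag}: internal stop codon at codon {pos}"
        )
    return body


def align_paralogs(a: CodonSequence, b: CodonSequence) -> CodonAlignment:
    """Protein-guided global codon alignment of two paralogs.

    The translated proteins are globally aligned (BLOSUM62, affine gaps
    -11/-1) and the alignment is threaded back onto codons; gap columns,
    ambiguous codons, and codon pairs whose substitution pathways all
    transit stops are removed. Pairs under 30% amino-acid identity are
    flagged ``low_identity``.
    """
    prot_a = _check_internal_stops(a, translate_codons(a.codons))
    prot_b = _check_internal_stops(b, translate_codons(b.codons))
    cod_a = a.codons[: len(prot_a)]
    cod_b = b.codons[: len(prot_b)]

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    aln = aligner.align(prot_a, prot_b)[0]

    pair_table = _pair_diff_table()
    used_a: list[str] = []
    used_b: list[str] = []
    n_aligned = 0
    n_ident = 0
    blocks_a, blocks_b = aln.aligned
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for off in range(ea - sa):
            i, j = sa + off, sb + off
            n_aligned += 1
            if prot_a[i] == prot_b[j]:
                n_ident += 1
            ca, cb = cod_a[i], cod_b[j]
            if set(ca) <= set("ACGT") and set(cb) <= set("ACGT"):
                if pair_table.get((ca, cb)) is not None:
                    used_a.append(ca)
                    used_b.append(cb)
    aln_len = aln.shape[1]
    identity = n_ident / n_aligned if n_aligned else 0.0
    flags = frozenset({"low_identity"} if identity < 0.30 else set())
    return CodonAlignment(
        locus_1=a.locus_tag,
        locus_2=b.locus_tag,
        codons_a=tuple(used_a),
        codons_b=tuple(used_b),
        n_codons_dropped=aln_len - len(used_a),
        identity=identity,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Results container and the clock
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParalogPairResult:
    """S, N, dS, dN, omega and clock times for one paralog pair."""

    locus_1: str
    locus_2: str
    S: float
    N: float
    dS: float
    dN: float
    tS: float  # My, unrounded (round at report time)
    tN: float
    method: str
    omega: float | None = None  # None when dS == 0 (0/0)
    flags: frozenset[str] = frozenset()


def divergence_times(
    dS: float, dN: float, rates: ClockRates = ClockRates()
) -> tuple[float, float]:
    """Convert dS/dN to divergence times in My (unrounded).

    Reports round to the nearest My; the raw values are returned so the
    conversion stays exactly linear.
    """
    if dS < 0 or dN < 0:
        raise ValueError("dS and dN must be >= 0")
    return dS / rates.syn_rate, dN / rates.nonsyn_rate


def _omega(dN: float, dS: float) -> float | None:
    return None if dS == 0 else dN / dS


def _jukes_cantor(p: float, label: str) -> float:
    if p >= 0.75:
        raise ValueError(
            f"saturation: {label} proportion {p:.3f} >= 0.75, "
            "Jukes-Cantor correction undefined"
        )
    return -0.75 * np.log1p(-(4.0 / 3.0) * p) if p > 0 else 0.0


def estimate_dnds_ng86(
    aln: CodonAlignment, rates: ClockRates = ClockRates()
) -> ParalogPairResult:
    """NG86 dS/dN with Jukes-Cantor correction and clock times."""
    if aln.n_codons_used < 1:
        raise ValueError("empty codon alignment")
    sites = [ng86_sites(c) for c in aln.codons_a]
    Sa = sum(s for s, _ in sites)
    sites_b = [ng86_sites(c) for c in aln.codons_b]
    Sb = sum(s for s, _ in sites_b)
    L = aln.n_codons_used
    S = (Sa + Sb) / 2.0
    N = 3.0 * L - S
    pair_table = _pair_diff_table()
    Sd = Nd = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sd, nd = pair_table[(ca, cb)]  # blocked pairs removed at alignment
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS, "synonymous")
    dN = _jukes_cantor(pN, "non-synonymous")
    tS, tN = divergence_times(dS, dN, rates)
    flags = set(aln.flags)
    if dS == 0 and dN == 0:
        flags.add("identical")
    return ParalogPairResult(
        locus_1=aln.locus_1,
        locus_2=aln.locus_2,
        S=S,
        N=N,
        dS=dS,
        dN=dN,
        tS=tS,
        tN=tN,
        method="ng86",
        omega=_omega(dN, dS),
        flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# GY94 maximum likelihood
# ---------------------------------------------------------------------------

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_N_SENSE = len(SENSE_CODONS)


@lru_cache(maxsize=1)
def _gy_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(is_single, is_transition, is_synonymous) boolean 61x61 arrays for
    codon pairs differing at exactly one position."""
    single = np.zeros((_N_SENSE, _N_SENSE), dtype=bool)
    transition = np.zeros_like(single)
    synonymous = np.zeros_like(single)
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if c1[k] != c2[k]]
            if len(diff) != 1:
                continue
            single[i, j] = True
            k = diff[0]
            transition[i, j] = (c1[k], c2[k]) in ts_pairs
            synonymous[i, j] = GENETIC_CODE[c1] == GENETIC_CODE[c2]
    return single, transition, synonymous


def _f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    pos_freq = np.zeros((3, 4))
    for codons in (aln.codons_a, aln.codons_b):
        for codon in codons:
            for k, base in enumerate(codon):
                pos_freq[k, _BASES.index(base)] += 1
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, _BASES.index(c[0])]
            * pos_freq[1, _BASES.index(c[1])]
            * pos_freq[2, _BASES.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    # Guard against zero frequencies for codons absent from short alignments.
    pi = np.maximum(pi, 1e-10)
    return pi / pi.sum()


def _build_q(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Normalized GY-style rate matrix (1 expected substitution per unit t)."""
    single, transition, synonymous = _gy_structure()
    q = np.zeros((_N_SENSE, _N_SENSE))
    rate = np.where(transition, kappa, 1.0) * np.where(synonymous, 1.0, omega)
    q[single] = (pi[None, :] * rate)[single]
    np.fill_diagonal(q, -q.sum(axis=1))
    nu = -(pi * np.diag(q)).sum()
    return q / nu


def _flux_fractions(
    kappa: float, omega: float, pi: np.ndarray
) -> tuple[float, float]:
    """Fractions of substitution flux that are synonymous/non-synonymous."""
    single, transition, synonymous = _gy_structure()
    rate = np.where(transition, kappa, 1.0) * np.where(synonymous, 1.0, omega)
    flux = pi[:, None] * pi[None, :] * rate * single
    total = flux.sum()
    syn = flux[synonymous & single].sum()
    return syn / total, 1.0 - syn / total


def estimate_dnds_gy94(
    aln: CodonAlignment, rates: ClockRates = ClockRates()
) -> ParalogPairResult:
    """Pairwise ML under a GY94 codon model (F3x4), multi-start L-BFGS-B.

    dS and dN are derived from the fitted divergence t, the synonymous and
    non-synonymous substitution flux under the fitted (kappa, omega), and
    mutational-opportunity site counts (the same flux evaluated at
    omega = 1).
    """
    from scipy.linalg import expm
    from scipy.optimize import minimize

    if aln.n_codons_used < 30:
        raise ValueError("GY94 needs >= 30 aligned codons for a stable fit")
    pi = _f3x4_frequencies(aln)
    counts = np.zeros((_N_SENSE, _N_SENSE))
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        counts[_CODON_INDEX[ca], _CODON_INDEX[cb]] += 1.0
    log_pi = np.log(pi)

    def neg_loglik(theta: np.ndarray) -> float:
        t, kappa, omega = np.exp(theta)
        q = _build_q(kappa, omega, pi)
        p = expm(q * t)
        p = np.maximum(p, 1e-300)
        return -float((counts * (log_pi[:, None] + np.log(p))).sum())

    starts = [
        np.log([0.3, 2.0, 0.2]),
        np.log([1.0, 1.0, 1.0]),
        np.log([0.05, 4.0, 0.05]),
    ]
    bounds = [
        (np.log(1e-6), np.log(50.0)),
        (np.log(0.05), np.log(50.0)),
        (np.log(1e-4), np.log(20.0)),
    ]
    best = None
    diagnostics = []
    for x0 in starts:
        res = minimize(neg_loglik, x0, method="L-BFGS-B", bounds=bounds)
        diagnostics.append(res.message)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"GY94 fit failed on all starts: {diagnostics}")
    t_hat, kappa_hat, omega_hat = np.exp(best.x)
    rho_s, rho_n = _flux_fractions(kappa_hat, omega_hat, pi)
    rho_s1, rho_n1 = _flux_fractions(kappa_hat, 1.0, pi)
    S = 3.0 * rho_s1 * aln.n_codons_used
    N = 3.0 * rho_n1 * aln.n_codons_used
    dS = t_hat * rho_s / (3.0 * rho_s1)
    dN = t_hat * rho_n / (3.0 * rho_n1)
    tS, tN = divergence_times(dS, dN, rates)
    flags = set(aln.flags)
    if t_hat <= 1e-4:
        flags.add("identical")
    return ParalogPairResult(
        locus_1=aln.locus_1,
        locus_2=aln.locus_2,
        S=S,
        N=N,
        dS=dS,
        dN=dN,
        tS=tS,
        tN=tN,
        method="gy94",
        omega=_omega(dN, dS),
        flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# Substitution bookkeeping and cluster summaries
# ---------------------------------------------------------------------------

def count_substitutions(aln: CodonAlignment) -> tuple[int, int, int]:
    """(total nt mismatches, synonymous-only codon columns, aligned nt length)."""
    total = 0
    syn_only_cols = 0
    pair_table = _pair_diff_table()
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        mism = sum(1 for x, y in zip(ca, cb) if x != y)
        total += mism
        if mism:
            sd, nd = pair_table[(ca, cb)]
            if nd == 0:
                syn_only_cols += 1
    return total, syn_only_cols, 3 * aln.n_codons_used


def summarize_cluster_ages(
    results: list[ParalogPairResult],
) -> tuple[float, float, float]:
    """(min, median, max) of the pooled {tS, tN} ages, rounded to whole My."""
    if not results:
        raise ValueError("no paralog pair results to summarize")
    pooled = np.array([v for r in results for v in (r.tS, r.tN)], dtype=float)
    return (
        float(round(pooled.min())),
        float(round(float(np.median(pooled)))),
        float(round(pooled.max())),
    )


def pair_result_from_rates(
    locus_1: str,
    locus_2: str,
    dS: float,
    dN: float,
    rates: ClockRates = ClockRates(),
    S: float = float("nan"),
    N: float = float("nan"),
    method: str = "printed",
) -> ParalogPairResult:
    """Build a result row from already-estimated dS/dN (clock arithmetic only)."""
    tS, tN = divergence_times(dS, dN, rates)
    return ParalogPairResult(
        locus_1=locus_1,
        locus_2=locus_2,
        S=S,
        N=N,
        dS=dS,
        dN=dN,
        tS=tS,
        tN=tN,
        method=method,
        omega=_omega(dN, dS),
    )


def load_reference_table() -> pd.DataFrame:
    """Published per-pair divergence estimates for the two paralogous
    clusters of the C. psychrerythraea 34H genome (input data for the
    clock arithmetic; columns ``ts_printed``/``tn_printed``/``omega_printed``
    are the values as published)."""
    with resources.files("hgtclock.data").joinpath(
        "paralog_divergence_table.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
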