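"""Synthetic genomes, HGT events, paralog pairs, and genome ensembles.

Every generator is a pure function of its arguments and a seed, and each
returns a TruthRecord holding the planted parameters so downstream
estimates can be scored against ground truth.

Genome composition is controlled directly at the codon-position level
(bases drawn independently with per-position G+C probabilities), because
the amelioration model operates on composition. Paralog pairs, by
contrast, are produced by an explicit substitution process — single
nucleotide changes classified synonymous/non-synonymous as they are
applied — so that counting estimators have a mechanistic target.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .amelioration import AmeliorationParams
from .equilibrium_curves import CURVE_FORMS, CurveModel, GenomePoint
from .paralog_dating import GENETIC_CODE, STOP_CODONS, ng86_sites
from .seq_io import CdsFeature, CodonSequence, NucleotideRecord

__all__ = [
    "TruthRecord",
    "SyntheticGenome",
    "default_curves",
    "simulate_genome",
    "simulate_hgt_event",
    "simulate_paralog_pair",
    "simulate_genome_ensemble",
    "write_genome",
]

# Fixed A/T-rich intergenic spacer: keeps non-coding composition from
# polluting per-CDS statistics and makes outputs byte-reproducible.
SPACER = ("ATTTAATTAT" * 5)[:50]


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one generated artifact."""

    scenario: str
    parameters: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=float)
        )

    @staticmethod
    def from_json(path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return TruthRecord(d["scenario"], d["parameters"], d["seed"])


@dataclass(frozen=True)
class SyntheticGenome:
    record: NucleotideRecord
    features: tuple[CdsFeature, ...]
    codon_sequences: tuple[CodonSequence, ...]
    truth: TruthRecord


def default_curves() -> tuple[CurveModel, CurveModel]:
    """The 'true' equilibrium curves used throughout synthetic work.

    Quadratics chosen once to mimic published genome-ensemble regressions
    of GC1 and GC2 on GC3 (GC1 spans ~0.43-0.66 and GC2 ~0.30-0.44 as GC3
    runs from 0.1 to 0.95).
    """
    f1 = CurveModel("GC1", "quadratic", (0.30, 0.45, -0.05), 0.0, 0, (0.0, 1.0))
    f2 = CurveModel("GC2", "quadratic", (0.28, 0.25, -0.05), 0.0, 0, (0.0, 1.0))
    return f1, f2


# Stop codons drawn by the independent-position base model are rewritten to
# sense codons with the identical A/T-vs-G/C pattern at every position, so
# gene bodies translate cleanly while per-position G+C stays exactly on
# target (TAA -> ATA, TAG -> ATG, TGA -> AGT).
_STOP_REWRITE = {"TAA": "ATA", "TAG": "ATG", "TGA": "AGT"}


def _draw_codons(
    rng: np.random.Generator, n_codons: int, p_gc: np.ndarray
) -> list[str]:
    """Draw codons with independent per-position G+C probabilities."""
    is_gc = rng.random((n_codons, 3)) < p_gc[None, :]
    strong = rng.random((n_codons, 3)) < 0.5  # G vs C, A vs T
    chars = np.where(is_gc, np.where(strong, "G", "C"), np.where(strong, "A", "T"))
    return [_STOP_REWRITE.get(c, c) for c in ("".join(row) for row in chars)]


def _gene_targets(
    rng: np.random.Generator,
    gc3: float,
    curves: tuple[CurveModel, CurveModel],
    noise_sd: float,
) -> tuple[np.ndarray, bool]:
    f1, f2 = curves
    base = np.array([f1.predict(gc3), f2.predict(gc3), gc3], dtype=float)
    noisy = base + rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else base
    clamped = np.clip(noisy, 0.01, 0.99)
    return clamped, bool(np.any(clamped != noisy))


def _assemble(
    contig_id: str,
    gene_bodies: Sequence[list[str]],
    strands: Sequence[str],
    locus_tags: Sequence[str],
    truth: TruthRecord,
) -> SyntheticGenome:
    from .seq_io import reverse_complement

    parts: list[str] = []
    features: list[CdsFeature] = []
    codon_seqs: list[CodonSequence] = []
    pos = 0
    for body, strand, tag in zip(gene_bodies, strands, locus_tags):
        codons = ["ATG"] + list(body) + ["TAA"]
        nt = "".join(codons)
        parts.append(SPACER)
        pos += len(SPACER)
        start = pos + 1
        end = pos + len(nt)
        parts.append(nt if strand == "+" else reverse_complement(nt))
        pos = end
        features.append(CdsFeature(tag, contig_id, start, end, strand))
        codon_seqs.append(CodonSequence(tag, tuple(codons)))
    parts.append(SPACER)
    record = NucleotideRecord(contig_id, "".join(parts))
    return SyntheticGenome(record, tuple(features), tuple(codon_seqs), truth)


def simulate_genome(
    n_genes: int,
    target_gc3: float,
    seed: int,
    gene_length_dist: int | Callable[[np.random.Generator], int] = 200,
    curves: tuple[CurveModel, CurveModel] | None = None,
    noise_sd: float = 0.0,
    contig_id: str = "synth_contig_1",
    locus_prefix: str = "SYN",
) -> SyntheticGenome:
    """One-contig genome of protein-coding genes at a target composition.

    Each gene's per-position G+C targets are (f1(gc3), f2(gc3), gc3) plus
    per-gene Gaussian noise of SD ``noise_sd`` (clamped to [0.01, 0.99]).
    Genes get a fixed ATG start and TAA stop and are tiled on one contig
    with 50-nt A/T-rich spacers; strand is drawn at random per gene.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < target_gc3 < 1.0:
        raise ValueError("target_gc3 must lie in (0,1)")
    curves = curves or default_curves()
    rng = np.random.default_rng(seed)
    bodies: list[list[str]] = []
    strands: list[str] = []
    n_clamped = 0
    for _ in range(n_genes):
        p_gc, clamped = _gene_targets(rng, target_gc3, curves, noise_sd)
        n_clamped += clamped
        n_codons = (
            gene_length_dist
            if isinstance(gene_length_dist, int)
            else int(gene_length_dist(rng))
        )
        bodies.append(_draw_codons(rng, n_codons, p_gc))
        strands.append("+" if rng.random() < 0.5 else "-")
    if n_clamped > 0.1 * n_genes:
        raise ValueError(
            f"composition infeasible: {n_clamped}/{n_genes} genes hit the "
            "target clamp"
        )
    truth = TruthRecord(
        scenario="genome",
        parameters={
            "n_genes": n_genes,
            "target_gc3": target_gc3,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    tags = [f"{locus_prefix}_{i + 1:04d}" for i in range(n_genes)]
    return _assemble(contig_id, bodies, strands, tags, truth)


def simulate_hgt_event(
    host: SyntheticGenome,
    donor_gc3: float,
    operon_n_genes: int,
    age_T: float,
    params: AmeliorationParams,
    seed: int,
    curves: tuple[CurveModel, CurveModel] | None = None,
    operon_gene_length: int = 200,
) -> SyntheticGenome:
    """Insert a forward-ameliorated donor operon into a host genome.

    The operon is generated at the donor composition implied by the true
    curves at ``donor_gc3``, then its composition targets are relaxed
    toward the host equilibrium for ``age_T`` My (codon draws are taken at
    the ameliorated targets — composition-level amelioration). The insert
    position and planted parameters go into the TruthRecord.
    """
    curves = curves or default_curves()
    f1, f2 = curves
    host_gc3 = host.truth.parameters.get("target_gc3")
    if host_gc3 is not None and abs(donor_gc3 - host_gc3) < 1e-9:
        raise ValueError("donor GC3 equals host GC3: event unidentifiable")
    rng = np.random.default_rng(seed)
    donor = np.array(
        [f1.predict(donor_gc3), f2.predict(donor_gc3), donor_gc3], dtype=float
    )
    e = np.asarray(params.host_equilibrium, dtype=float)
    k = np.asarray(params.rates, dtype=float)
    ameliorated = e + (donor - e) * np.exp(-k * age_T)

    op_bodies = [
        _draw_codons(rng, operon_gene_length, ameliorated)
        for _ in range(operon_n_genes)
    ]
    op_strands = ["+"] * operon_n_genes
    op_tags = [f"HGT_{i + 1:04d}" for i in range(operon_n_genes)]

    n_host = len(host.features)
    insert_after = n_host // 2  # insert mid-genome, between host genes
    host_bodies = [list(cs.codons[1:-1]) for cs in host.codon_sequences]
    host_strands = [f.strand for f in host.features]
    host_tags = [f.locus_tag for f in host.features]

    bodies = (
        host_bodies[:insert_after] + op_bodies + host_bodies[insert_after:]
    )
    strands = (
        host_strands[:insert_after] + op_strands + host_strands[insert_after:]
    )
    tags = host_tags[:insert_after] + op_tags + host_tags[insert_after:]
    truth = TruthRecord(
        scenario="hgt_event",
        parameters={
            "donor_gc3": donor_gc3,
            "donor_gc1": float(donor[0]),
            "donor_gc2": float(donor[1]),
            "age_T": age_T,
            "operon_n_genes": operon_n_genes,
            "operon_gene_length": operon_gene_length,
            "insert_after_gene": insert_after,
            "operon_locus_tags": op_tags,
            "host_seed": host.truth.seed,
        },
        seed=seed,
    )
    return _assemble(host.record.id, bodies, strands, tags, truth)


def simulate_paralog_pair(
    cds: CodonSequence,
    dS_target: float,
    dN_target: float,
    seed: int,
    max_proposals: int = 2_000_000,
) -> tuple[tuple[CodonSequence, CodonSequence], TruthRecord]:
    """Diverge a copy of ``cds`` to target per-site dS and dN.

    Single-nucleotide changes are proposed at random positions, classified
    synonymous or non-synonymous against the *current* codon (stops always
    rejected), and accepted until the realized per-site counts — with NG86
    site denominators and the Jukes-Cantor mapping p = 3/4 (1 - e^{-4d/3})
    — reach the targets.
    """
    if dS_target < 0 or dN_target < 0:
        raise ValueError("divergence targets must be >= 0")
    # Targets are substitution *events* per site; the estimator's
    # Jukes-Cantor correction maps the observed (collision-reduced)
    # difference proportion back onto this event scale.
    p_s = 0.75 * (1.0 - np.exp(-4.0 * dS_target / 3.0))
    p_n = 0.75 * (1.0 - np.exp(-4.0 * dN_target / 3.0))
    if p_s >= 0.75 or p_n >= 0.75:
        raise ValueError("requested divergence saturates (p >= 0.75)")
    sense = [c for c in cds.codons if c not in STOP_CODONS and c in GENETIC_CODE]
    sites = [ng86_sites(c) for c in sense]
    S0 = sum(s for s, _ in sites)
    N0 = sum(n for _, n in sites)
    syn_goal = int(round(dS_target * S0))
    nonsyn_goal = int(round(dN_target * N0))

    rng = np.random.default_rng(seed)
    codons = list(cds.codons)
    syn_done = nonsyn_done = 0
    proposals = 0
    while (syn_done < syn_goal or nonsyn_done < nonsyn_goal) and (
        proposals < max_proposals
    ):
        proposals += 1
        ci = int(rng.integers(len(codons)))
        pos = int(rng.integers(3))
        base = "ACGT"[int(rng.integers(4))]
        cur = codons[ci]
        if base == cur[pos] or cur in STOP_CODONS:
            continue
        alt = cur[:pos] + base + cur[pos + 1 :]
        if alt in STOP_CODONS or cur not in GENETIC_CODE:
            continue
        syn = GENETIC_CODE[cur] == GENETIC_CODE[alt]
        if syn and syn_done < syn_goal:
            codons[ci] = alt
            syn_done += 1
        elif not syn and nonsyn_done < nonsyn_goal:
            codons[ci] = alt
            nonsyn_done += 1
    if syn_done < syn_goal or nonsyn_done < nonsyn_goal:
        raise RuntimeError("proposal budget exhausted before reaching targets")
    derived = CodonSequence(f"{cds.locus_tag}_paralog", tuple(codons))
    truth = TruthRecord(
        scenario="paralog_pair",
        parameters={
            "dS_target": dS_target,
            "dN_target": dN_target,
            "syn_changes": syn_done,
            "nonsyn_changes": nonsyn_done,
            "S0": S0,
            "N0": N0,
        },
        seed=seed,
    )
    return (cds, derived), truth


def simulate_genome_ensemble(
    n_genomes: int,
    seed: int,
    gc3_range: tuple[float, float] = (0.15, 0.85),
    true_form: str = "quadratic",
    true_coeffs: tuple[tuple[float, ...], tuple[float, ...]] | None = None,
    noise_sd: float = 0.01,
) -> tuple[list[GenomePoint], TruthRecord]:
    """Genome points (gc3 uniform over a range) on a known curve + noise."""
    if n_genomes < 10:
        raise ValueError("need >= 10 genomes")
    if true_form not in CURVE_FORMS:
        raise ValueError(f"unknown curve form {true_form!r}")
    if true_coeffs is None:
        f1, f2 = default_curves()
        if true_form != "quadratic":
            raise ValueError("true_coeffs required for non-quadratic forms")
        true_coeffs = (f1.coefficients, f2.coefficients)
    fn = CURVE_FORMS[true_form][0]
    rng = np.random.default_rng(seed)
    gc3 = rng.uniform(gc3_range[0], gc3_range[1], size=n_genomes)
    gc1 = np.clip(fn(gc3, *true_coeffs[0]) + rng.normal(0, noise_sd, n_genomes), 0, 1)
    gc2 = np.clip(fn(gc3, *true_coeffs[1]) + rng.normal(0, noise_sd, n_genomes), 0, 1)
    points = [
        GenomePoint(f"genome_{i + 1:04d}", float(a), float(b), float(c))
        for i, (a, b, c) in enumerate(zip(gc1, gc2, gc3))
    ]
    truth = TruthRecord(
        scenario="genome_ensemble",
        parameters={
            "n_genomes": n_genomes,
            "gc3_range": list(gc3_range),
            "true_form": true_form,
            "true_coeffs": [list(c) for c in true_coeffs],
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return points, truth


def write_genome(genome: SyntheticGenome, outdir: str | Path, stem: str = "genome") -> dict[str, Path]:
    """Write FASTA + GFF3 + TruthRecord JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{stem}.fasta"
    gff = outdir / f"{stem}.gff3"
    truth = outdir / f"{stem}.truth.json"
    with open(fasta, "w") as fh:
        fh.write(f">{genome.record.id}\n")
        seq = genome.record.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {genome.record.id} 1 {len(genome.record)}\n"
        )
        for f in genome.features:
            fh.write(
                f"{f.contig_id}\thgtclock\tCDS\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t0\tID={f.locus_tag};locus_tag={f.locus_tag}\n"
            )
    genome.truth.to_json(truth)
    return {"fasta": fasta, "gff3": gff, "truth": truth}
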