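# hgtclock

Molecular-evolution tooling for dating horizontal gene transfer (HGT) and
gene duplication in bacterial genomes, built around the compositional
analysis of the psychrophile *Colwellia psychrerythraea* 34H, whose
compatible-solute (choline/glycine betaine/sarcosine) catabolism genes were
acquired stepwise over the last several hundred million years.

The package implements four connected analyses plus a fully ground-truthed
synthetic-data generator, so every stage can be validated without any
genome downloads:

1. **Codon-position G+C and genome signatures** (`composition`) — GC1/GC2/GC3
   per gene or pooled, and Karlin dinucleotide relative abundances
   ρ*\_XY = f\_XY/(f\_X f\_Y) with the δ* = (1/16) Σ |ρ*\_XY(a) − ρ*\_XY(b)|
   signature distance.
2. **Genomic-island detection** (`island_scan`) — runs of genes whose total
   G+C deviates more than 2 SD from the genome background, OR whose
   sliding-window dinucleotide signature is aberrant.
3. **Reverse G+C amelioration dating** (`equilibrium_curves`,
   `amelioration`) — transferred DNA relaxes toward the host equilibrium as
   GC\_i(T) = E\_i + (GC\_i(0) − E\_i)·e^(−k\_i·T) per codon position;
   running the dynamics backwards from the observed composition,

       GC_i(t) = E_i + (GC_i,obs − E_i)·e^(+k_i·t)
       D(t)    = [GC1(t) − f1(GC3(t))]² + [GC2(t) − f2(GC3(t))]²

   the introduction age t\* is the argmin of D over a 1-My grid, where
   f1, f2 are nonlinear equilibrium curves (GC3 → GC1, GC3 → GC2) fitted
   across a genome ensemble. The back-extrapolated composition at t\* is
   the inferred donor composition. 90% CIs come from 1,000 (configurable)
   codon-bootstrap replicates.
4. **Paralog divergence dating** (`paralog_dating`) — pairwise dS/dN by
   Nei–Gojobori (NG86) counting with Jukes–Cantor correction, or
   Goldman–Yang (GY94) maximum likelihood; divergence times from the
   empirical clock tS = dS/0.0091, tN = dN/0.00045 (substitutions per site
   per My).

## Worked example

Dating the duplicated betTABI (choline → glycine betaine) operon from the
published pairwise divergence estimates:

```python
from hgtclock import (load_reference_table, pair_result_from_rates,
                      summarize_cluster_ages)

bet = load_reference_table().query("cluster == 'betTABI'")
results = [pair_result_from_rates(r.locus_1, r.locus_2, r.dS, r.dN)
           for r in bet.itertuples()]
lo, med, hi = summarize_cluster_ages(results)
print(lo, med, hi)   # -> 240.0 298.0 1878.0
```

The pooled synonymous and non-synonymous ages of the six gene pairs span
~240–1878 My with a median of 298 My — a duplication age coinciding with
the Karoo glaciation. Running `python examples/date_hgt.py` dates a
simulated 2,400-codon operon transferred 150 My ago from a GC3 = 0.62
donor into a GC3 = 0.35 host:

```
planted age:      150 My, donor GC3 0.62
estimated age:    159 My (90% CI 121-205)
inferred donor:   GC3 0.644, total G+C 54.5% (90% CI 51.4-58.1)
```

The other scripts in `examples/` demonstrate island detection
(`island_scan.py`), equilibrium-curve fitting (`fit_curves.py`), dS/dN
estimation (`dnds_estimation.py`), and the clock table (`paralog_clock.py`).

## Command line

A thin CLI wraps the library for shell use:

```bash
hgtclock simulate --scenario hgt --seed 11 --outdir sim/
hgtclock island-scan --genome sim/hgt_genome.fasta \
    --annotations sim/hgt_genome.gff3 --out-prefix sim/islands
hgtclock fit-curves --ensemble sim/ensemble.tsv --out sim/curves.json
hgtclock date-hgt --genome sim/hgt_genome.fasta \
    --annotations sim/hgt_genome.gff3 --loci HGT_0001,HGT_0002 \
    --curves sim/curves.json --bootstrap 1000 --seed 1 --out dating.json
hgtclock date-paralogs --from-rates rates.tsv --out table.tsv
```

Real genomes (FASTA + GenBank or GFF3) go through the same subcommands.

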