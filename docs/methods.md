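# Methods

## The compositional model of amelioration

Horizontally transferred DNA initially carries its donor's nucleotide
composition and then drifts toward the host's mutational equilibrium
("amelioration"). We model each codon position independently as
exponential relaxation under directional mutation pressure:

    GC_i(T) = E_i + (GC_i(0) − E_i) · exp(−k_i T),   i = 1, 2, 3

with `E_i` the host equilibrium G+C at position i and `k_i` a per-My
relaxation rate. This is the closed-form solution of a two-state (AT↔GC)
mutation process with constant pressure; it assumes the host's mutational
regime has been stationary over the dating horizon and that selection on
the transferred genes does not change their amino-acid composition
appreciably.

Dating inverts the dynamics. From the observed composition the trajectory

    GC_i(t) = E_i + (GC_i,obs − E_i) · exp(+k_i t)

is evaluated on a grid t = 0, 1, …, 1000 My (1-My steps). Equilibrium
curves f1: GC3→GC1 and f2: GC3→GC2, fitted across a genome ensemble,
define where "ordinary" genomes sit; because GC3 is nearly neutral while
GC1/GC2 are protein-constrained, a genome at equilibrium lies on both
curves. The discrepancy

    D(t) = [GC1(t) − f1(GC3(t))]² + [GC2(t) − f2(GC3(t))]²

is minimized over the grid; the argmin (smallest t on ties) is the
introduction age t\*, and the composition at t\* is the inferred donor
composition. The squared-error form of D is a design choice: any positive
combination of the two prediction errors would do, and squared error gives
a smooth, scale-balanced criterion. Grid search at the 1-My resolution is
deliberate — it matches the procedure's published resolution and makes tie
handling exact rather than dependent on an optimizer's tolerance.

Backward exponentials diverge, so trajectories are clamped to
[1e-6, 1 − 1e-6]; the first grid point at which any position hits the
clamp truncates the usable trajectory and sets a `saturated` flag. A
composition exactly at host equilibrium is a fixed point (constant D) and
is flagged `native_signal`; estimates at the grid edges carry a
`boundary` flag.

### Rates and equilibrium (defaults, units)

* `k3 = 0.0091 /My` — anchored to the empirical synonymous clock
  (0.91% substitutions per synonymous site per My), since third positions
  are predominantly synonymous.
* `k1 = 0.0020 /My`, `k2 = 0.0010 /My` — first and second positions relax
  an order of magnitude more slowly because amino-acid constraint opposes
  mutation pressure; the ordering k3 ≥ k1 ≥ k2 is the operative
  assumption and all three are configurable.
* `E = (E1, E2, E3)` — defaults to the host genome's pooled per-CDS
  GC1/GC2/GC3, i.e. the host is assumed to be at compositional
  equilibrium.

### Bootstrap confidence intervals

Uncertainty is dominated by the finite number of codons. B replicates
(default 1000) resample the sequence's codons with replacement, recompute
the G+C profile and re-date; the 90% CI is the empirical 5th–95th
percentile band of t\* and of donor total G+C (marginal percentiles). The
point estimate always comes from the unresampled sequence. Replicates that
saturate immediately are counted; more than 10% failing aborts with an
error.

## Equilibrium curves

Candidate forms are quadratic, cubic, and 4-parameter logistic in GC3
(fractions, not percentages). Each is fit by least squares
(`scipy.optimize.curve_fit`) and AIC = n·ln(RSS/n) + 2k selects the form.
On exactly noiseless data every nested form reaches machine-zero RSS, so
RSS is floored at n·1e-20 before the AIC comparison — fit ties then
resolve to the most parsimonious form instead of floating-point noise.
Predictions are clamped to [0, 1], and evaluation outside the fitted GC3
range is flagged as extrapolation. The packaged default curves
(f1 = 0.30 + 0.45·x − 0.05·x², f2 = 0.28 + 0.25·x − 0.05·x²) were chosen
once to mimic the shape and range of published genome-ensemble
regressions (GC1 ≈ 0.43–0.66, GC2 ≈ 0.30–0.44 over GC3 0.1–0.95) and
serve as the generating truth for synthetic work; real analyses should fit
their own ensemble (`fit_curves` on a TSV of genome points).

## Island detection

Two evidence channels over genes in genomic order, combined by OR:

* **G+C channel** — a gene is flagged when its total G+C lies more than
  `gc_sd_threshold` (default 2) scale units from the genome background.
* **Bias channel** — sliding windows of `bias_window` (default 8)
  consecutive CDS are scored by δ* against the whole-genome dinucleotide
  profile; a window is flagged when it exceeds the across-window
  background by `bias_sd_threshold` (default 4) scale units, and every
  gene in a flagged window is flagged.

Islands are maximal runs of flagged ("hot") genes tolerating up to
`max_gap` (default 1) consecutive cold genes, requiring at least
`min_run` (default 6) hot genes; coordinates span the first to last hot
gene.

Two numerical choices matter and are deliberate:

1. **Robust background.** Both channels default to median/1.4826·MAD as
   the background location/scale (`robust=False` restores mean/sample-SD).
   On clean Gaussian data the two coincide, but a 10–30-gene island
   inflates a plain SD estimated from all genes or windows enough to mask
   itself — in simulations with a planted 12-gene high-G+C operon the
   per-gene SD rose from ~2% to >5%, hiding parts of the island from the
   very threshold meant to catch it.
2. **A 4-scale-unit bias cut.** An empirical mean+2SD cut on window δ*
   flags ~2.3% of windows on *unremarkable* genomes purely by
   construction, and since one flagged window spans more genes than
   `min_run`, every such window would become an island call. The window δ*
   null is also right-skewed. The default cut is therefore set so that a
   ~100-gene single-composition genome yields no flagged window with high
   probability (the largest robust z observed across 1,860 simulated null
   windows was 3.7), while genuinely bias-shifted inserts score z ≫ 10.

Mobility-gene and tRNA-proximity evidence used by annotation-based island
finders is out of scope; the detector uses composition only.

## dS/dN estimation and the clock

**NG86.** Synonymous site counts per codon classify the three
single-nucleotide neighbors at each position; changes to stop codons are
excluded and the position renormalized so every codon contributes exactly
3 sites (hence S + N = 3L). Differences between codon pairs average over
all mutational pathways with equal weights; pathways through stop codons
are dropped and the remainder reweighted (a pair whose every pathway is
blocked is excluded from the alignment). Proportions pS = Sd/S, pN = Nd/N
are corrected for multiple hits with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)p), undefined (error) at p ≥ 0.75. All 61×61 pair
counts are precomputed once.

**GY94.** Pairwise maximum likelihood under a Goldman–Yang codon model:
off-diagonal rates π_j·κ^[transition]·ω^[non-synonymous] for
single-nucleotide changes, F3x4 codon frequencies from the alignment
(floored at 1e-10 for unobserved codons), matrix normalized to one
expected substitution per codon per unit t. (t, κ, ω) are optimized in
log space by L-BFGS-B from three starts. dS and dN divide the synonymous
and non-synonymous substitution flux t·ρS, t·ρN by mutational-opportunity
site counts 3·ρS(ω=1), 3·ρN(ω=1).

**Alignment.** Paralogs are aligned at the protein level (global,
BLOSUM62, gap open −11 / extend −1), threaded back to codons; gap columns
and ambiguous codons are dropped, terminal stops removed, internal stops
are an error, and <30% amino-acid identity sets a `low_identity` flag.
Translation uses the bacterial code (table 11).

**Clock.** tS = dS / 0.0091 and tN = dN / 0.00045 (My). The conversion is
kept unrounded internally — reports round to whole My — so clock linearity
is exact. Published tables print dS/dN at 2 decimals; times recomputed
from those printed values can differ from printed times by a few My
(e.g. a printed 281 vs 288.9 recomputed), which is rounding provenance,
not disagreement. Cluster summaries pool all tS and tN values and report
min/median/max rounded to whole My.

## Synthetic data: what it emulates, what it does not

Genome generation controls composition directly: per gene, codon bases are
drawn independently with per-position G+C probabilities
(f1(gc3), f2(gc3), gc3) plus optional per-gene Gaussian noise, a fixed ATG
start and TAA stop, random strand, and 50-nt A/T-rich spacers between
genes. Stop codons arising in gene bodies are rewritten to sense codons
with the identical A/T-vs-G/C pattern at every position (TAA→ATA,
TAG→ATG, TGA→AGT), so CDSs translate cleanly while positional G+C stays
exactly on target. HGT events generate an operon at the donor composition
implied by the true curves, relax its composition targets forward by the
planted age, and insert it mid-genome. Paralog pairs instead use an
explicit substitution process — single-base proposals classified
synonymous/non-synonymous against the current codon, stops rejected,
accepted until the planted event counts (dS·S0, dN·N0) are reached — so
counting estimators have a mechanistic target.

Consequences for interpretation: generated sequences have near-zero
intrinsic dinucleotide bias (independent draws), so composition-shifted
inserts exercise the G+C channel of the island scanner, and
dinucleotide-channel tests plant inserts from an explicitly different
Markov model. There is no codon-usage realism, no indel evolution in
paralog pairs, no rate heterogeneity among sites, and no selection;
passing tests demonstrate correctness of the estimators under their own
model assumptions, not robustness to every property of real genomes.

Problem sizes used by the shipped checks: dating recovery uses a
2,400-codon operon (12 × 200 codons) at donor GC3 0.62 in a GC3 0.35
host, aged 150 My, with B = 200 bootstrap replicates across 50 replicate
simulations; island characteristics use 100-gene genomes over 20 seeds;
curve recovery uses 300-genome ensembles.

## Known limitations

* The relaxation rates k1, k2 are weakly identifiable from a single
  sequence; they are fixed inputs, not estimated, and mis-specifying them
  biases t\* (the donor GC3 estimate is more robust than the age).
* Amelioration dating assumes the donor lay on the equilibrium curves at
  transfer time; a donor itself out of equilibrium shifts the inferred
  age.
* The 1-My grid bounds dating resolution, and ages beyond
  step × max_steps (default 1000 My) are not representable.
* Percentile bootstrap CIs are first-order accurate; at ~2,000 codons
  their realized coverage in simulations is a few points below nominal at
  the upper tail.
* GY94 here is pairwise-only (no branch/site models) and uses F3x4, which
  is known to absorb some composition effects into ω.
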