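# Methods

## Model and procedure

The pipeline treats a somatic mutation catalog as a set of alleles: one row
per (sample, gene, position, alternate residue), with identical rows
collapsed. Allele counts and unique-sample counts are carried separately
throughout — enrichment statistics are computed on alleles (matching the
per-residue expectation formula's units), exclusivity tests on unique
samples.

Mutations are projected onto family alignment columns through partial
residue→column maps (match states only; insertion-state residues are
unmapped and tallied). A residue covered by instances of two different
families yields one hit per family; overlapping instances of the *same*
family resolve to the lowest-start instance, which is deterministic and
independent of input order. A column is conserved when one residue recurs
in at least half of the family sequences; consensus ties break
alphabetically (the choice is arbitrary but must be deterministic).

Enrichment per column: expected count `E = (A/L)·k` (A alleles in scope, L
proteome length, k instances mapping the column), log₂ odds, and a
one-tailed binomial `P(X ≥ O)` with `n = A` trials and a shuffle-estimated
prior. The shuffle relocates each sample's mutations uniformly within the
same protein (`gene_level`), or — to correct for elevated domain mutation
rates — within the same domain instance for in-domain mutations and within
the remaining sequence for the rest (`domain_aware`). Because only
positions are redrawn, per-(sample, protein) counts are conserved exactly
on every draw. The prior pools hits over shuffles with a pseudocount,
`π = (Σhits + ½)/(S·n + 1)`, so it is strictly inside (0,1) even for
never-hit columns. Candidates pass an observed-OR-expected floor (5/2.5
per cancer type, 20/5 pan-cancer); significance needs log-odds ≥ 0 and
BH `q ≤ 0.01`, with the FDR computed within scope across candidates.

Exclusivity: qualifying positions (significant, ≥ 5 unique samples per
cancer type or ≥ 50 pan-cancer) are paired when they share a conservation
class and at least one selected pathway (roots < 200 members taken
directly, otherwise children < 300, recursing into larger children;
oversized leaves are kept as there is nothing more specific). The Fisher
test is the lower hypergeometric tail of the co-mutated sample count. The
pair background mirrors the position binomial but shuffles only within the
pathway's member proteins and scores the union of the two columns. One row
is emitted per (pair, pathway); the Fisher FDR runs over unique pairs per
scope and is broadcast to rows so duplicated pathways do not inflate the
test count, while the pathway-background FDR runs across rows. Retention
requires both `q ≤ 0.1`. The same Fisher machinery serves the
position-versus-driver-alteration co-occurrence test.

Activity score: `A_G = Σ m_GPROT·s · m_GPCR·s · c` expanded as a double
sum over (G-protein member, coupled receptor) pairs, since the receptor
expression term is per-receptor — the only reading that uses every symbol.
The scaling factor is read multiplicatively (`m·s`), so significant
down-regulation (negative LFC) contributes negatively; the exponent
reading (`m^s`) is available via `mode="exponent"` for sensitivity
analysis. Secondary couplings gate `c = 1` exactly like primary ones.

## Universe for the exclusivity test

The restriction "samples with mutations at positions of the same
conservation class" is the default universe (`same_class`): the 2×2 table
is built over samples in scope carrying at least one hit at a domain
position of the pair's class. This is the reading under which sparse but
genuinely exclusive pairs are detectable — against the universe of *all*
mutated samples, a 30/30/0 pair in a 500-sample Poisson-2 cohort has an
expected overlap of ~2 and a lower-tail probability of ~0.13, so no such
pair could ever pass `q ≤ 0.1`. The broader `all_mutated` universe and a
`family` universe (samples mutated anywhere in either family) remain
selectable for sensitivity analyses.

## Synthetic cohorts

The generator emits all six input kinds with planted ground truth. Defaults
are the package's reference study conditions: 500 samples of one synthetic
cancer type, 10 families × 4 members, 400-residue proteins with one
contiguous 100-column domain each, conservation fractions drawn so half the
columns are conserved, and a Poisson(2) per-sample background placed
uniformly over residues (mutation classes 90% missense / 6% stop gain / 4%
frameshift). Uniform placement is intentional: it is exactly the background
the shuffle statistics assume, so calibration tests measure the statistics,
not a signature mismatch. Planted hotspot and pair columns are generated
conserved (fraction 0.9) so planted pairs always share a class. Expression
base means are log-normal (μ=4, σ=1 on the log scale); unplanted genes get
LFC ~ N(0, 0.1) with padj = 1. Each generator stage draws from its own RNG
stream derived from the master seed, so stages can be regenerated
independently and reruns are byte-identical.

What the generator does **not** emulate: trinucleotide mutational
signatures, copy-number or structural variation, transcript-isoform
mapping, family-size heterogeneity, or correlated mutation burdens between
samples. Passing tests therefore demonstrate the correctness and
calibration of the statistics under their own model assumptions, not
performance on real catalogs, where signature-driven hotspots can inflate
position counts beyond the uniform expectation.

## Numerical choices and degenerate inputs

- Log-odds: base 2 (any base preserves the sign threshold); 0 observed is
  −∞, non-positive expected is NaN with a warning.
- A fully mapped protein leaves a `domain_aware` out-of-domain mutation
  nowhere to go; it keeps its position (cannot arise with our generator's
  geometry, handled defensively for real data).
- A mutation covered by overlapping instances of different families is
  assigned, for domain-aware shuffling, to the first containing instance in
  (start, family) order.
- Unparseable protein-change strings (`p.?`, in-frame indels, extensions)
  are skipped and counted, never fatal; missing required columns are hard
  errors naming the column.
- Dubious-gene flagging takes the ceiling of the top 2% most
  mutation-tolerant genes with cutoff ties included, and is row-order
  invariant.
- Structural numbering (Ballesteros–Weinstein, common Gα) is driven by
  user-supplied anchor tables — nearest anchor plus signed column offset on
  the label's last dotted component — rather than re-deriving helix
  segmentation from HMM metadata; a query before its segment start falls
  back to the consecutive label with a warning. Behaviour for columns with
  ambiguous consensus across sub-alignments is not defined here.
- All tables are stably sorted before writing and floats are formatted with
  a fixed precision, so equal seed + config ⇒ byte-identical artifacts.

## Problem sizes in the checks

The acceptance checks use sizes chosen to keep every quantity estimable
with comfortable margins: the exact-test sweeps cover all 2×2 tables with
N ≤ 30 and all binomial tails with n ≤ 50; BH-FDR is compared with a brute
min-over-suffix oracle on 1000 random vectors of length up to 500; shuffle
conservation is asserted on 1000 draws of a 50-sample fixture and
uniformity on 20 seeds × 100 shuffles of a fully mapped two-member family
(expected ≥ 50 hits per residue, the chi-square regime); calibration and
recovery each use 20 seeds of the reference conditions above.

## Known limitations

- The binomial trial count is proteome-wide alleles in scope; a per-gene
  alternative is a plausible reading and is not currently implemented as a
  switch beyond the scope restriction inherent in the pathway background.
- The pathway-background FDR is computed across (pair, pathway) rows, which
  is slightly conservative when one pair supports many pathways.
- Jaccard similarity of transcription-factor targets is computed densely;
  very large TF panels (thousands) would need a sparse implementation.
- The CLI loads whole catalogs into memory; catalogs of tens of millions of
  alleles are better processed per cancer type.
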