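# Methods

## Overview

`tailscope` analyses how bacterial mRNAs recruit the ribosome during
translation initiation. The Shine-Dalgarno (SD) sequence upstream of a
start codon base-pairs with the anti-SD (aSD) segment at the free 3' end
of the 16S rRNA (the "3' tail"). Three questions structure the pipeline:

1. Where does the mature 16S rRNA actually end? The genomic rDNA
   annotation overshoots the RNA present in the cell, because several
   exoribonucleases trim the 3' end during maturation. Reads from
   non-ribo-depleted RNA-Seq pile up at the true terminus.
2. Which part of the tail is the *core* aSD — the segment preferentially
   engaged in SD pairing, beyond the universally conserved CCUCC motif?
3. How does SD usage relate to SD:aSD duplex binding affinity, overall and
   in highly vs lowly expressed genes (HEG/LEG)?

## Terminus mapping

Reads are collapsed to distinct sequences ("FASTA+": multiplicity encoded
as a trailing `_<count>` id suffix) and aligned to the final stretch of the
annotated 16S rDNA (85 nt for the 15-nt-tail species profile, 60 nt for
the 13-nt one) by a deterministic seed-and-extend scheme: an exact 20-mer
shared between read and reference proposes a diagonal; the ungapped
alignment spans the full read/reference overlap on that diagonal; at most
2 substitutions are tolerated. Both read orientations are tried and one
best hit is kept per read (most aligned bases, then fewest mismatches,
then leftmost reference position, '+' orientation on exact ties). The
exact-seed + mismatch budget replaces a heuristic local aligner with
e-value cutoff; at these read lengths and identities the two are
equivalent, and the scheme is reproducible and dependency-free. A
brute-force all-offsets scorer in the test suite checks the best interval
and mismatch count read by read.

**Retention rule.** Only reads that reach at least the final C of the
conserved CCUCC core, with *zero* mismatches within or 3' of the motif,
inform the terminus call. This is the strictest reading of "no errors in
base calling towards the 3' end": a sequencing error near the terminus
would masquerade as a different 3' end. Retained reads are histogrammed by
the reference position of their 3'-most aligned base, weighted by read
multiplicity.

**Tail call.** Every terminus carrying at least `min_frac` (default 0.10)
of retained reads becomes a candidate tail running from the conserved
5'-GAUCACCUCC anchor through that end. Several termini can be "major"
(rRNA 3' ends are continuously nibbled in vivo); the designated mature
tail is the *longest* candidate, matching the convention of adopting the
longest widely accepted terminus. `min_frac` and the longest-candidate
rule are both exposed rather than hard-coded, since no principled
tie-break exists when multiple termini are real.

## SD detection and D_toStart

The 30 nt immediately 5' of each annotated start codon are scanned for
maximal ungapped stretches that are perfect antiparallel Watson-Crick
complements of a tail segment, with lengths 4–12 nt. G:U wobble pairs are
not counted — the criterion is complementarity, and pairing flexibility is
treated as a caveat, not a rule. All maximal matches per gene are kept
(sub-matches inside a longer perfect duplex are never counted separately,
which would double-count the length spectrum N_m); a best-per-gene
reduction is available as an option. Maximal runs longer than 12 nt are
not reported; on a ≤15-nt tail inside a 30-nt window they essentially
cannot occur.

Each match implies a pairing geometry summarised by

    D_toStart = g + (L − p_start + 1),

with g the spacer (nt strictly between the SD 3' base and the start
codon), L the tail length and p_start the 5'-most paired tail site. This
is the count of mRNA positions spanned from the base opposite the rRNA 3'
terminus to the start codon; the canonical GGAGG:CCUCC pairing with a 7-nt
spacer on the 15-nt tail gives D_toStart = 17, the modal value for that
species profile. Matches are filtered to an optimal window — the
documented windows are 15–21 (15-nt tail) and 10–21 (13-nt tail) — or to
an automatic window [mode − 2, mode + 4] derived from the D_toStart
histogram when no window is given. The automatic rule is this package's
own; explicit windows remain the way to reproduce published ranges.

## Observed vs expected site usage

Each tail base is an aSD "site". Observed usage of site p counts the
matches whose paired segment covers p. Under the null that a length-m SD
pairs any of the L − m + 1 tail windows with equal probability,

    expected(p) = Σ_m c(p, m, L) · N_m / (L − m + 1),
    c(p, m, L)  = min(p, L − p + 1, m, L − m + 1),

where c is the number of length-m windows covering site p. The statistic
satisfies two exact identities used as tests: Σ_p expected(p) = Σ_m m·N_m
and expected(p) = expected(L + 1 − p). Central sites are geometrically
favoured, so raw observed counts overstate the middle of the tail; the
observed/expected ratio corrects for this.

A historically printed expansion of the site-6 expectation (L = 15) uses
coefficients 6 and 5 for m = 11 and m = 12 where only 5 and 4 windows
cover the site; these exceed the window counts and are inconsistent with
the site-1 expression and the equiprobable-window assumption, so the
general combinatorial formula is implemented. An `eq2_literal` flag
reproduces the printed site-6 coefficients for comparison only (it breaks
the conservation identity).

**Core aSD.** A site is favored when its ratio exceeds 1 (strictly; no
multiplicity correction is applied, and a ratio "very close to one" is
reported but not auto-included). The core aSD is the longest contiguous
favored run, ties broken toward the larger summed observed − expected.
When the run starts inside, or immediately 3' of, the CCUCC motif, the
*extended* core prepends tail bases back through the full motif — the form
used to enumerate the complementary SD set.

## Binding affinity

`duplex_dG(a, b)` returns the hybridization free energy of two RNA strands
at 37 °C. The default engine is the ViennaRNA cofold machinery via its
Python bindings, reporting the partition-function binding free energy
ΔG = F(AB) − F(A) − F(B) (what `RNAcofold -a` prints as "delta G
binding"); Boltzmann factors are rescaled around the MFE first, which
matters for deeply bound duplexes. The reference values for the two
canonical 5-mers are −7.05 kcal/mol (CCUCC:GGAGG) and −3.04 kcal/mol
(CCUUU:AAAGG); the MFE alone would give −7.00 and −2.60, because for
weakly bound AU-rich duplexes shifted pairing registers contribute
appreciably to the ensemble.

The internal engine is a nearest-neighbor MFE duplex model — helix stacks,
+4.10 duplex initiation, +0.50 per terminal AU pair, no loops or bulges —
evaluated over every ungapped antiparallel register. Its parameters
reproduce the external engine's MFE duplex energies exactly for perfect
Watson-Crick duplexes (verified against the full SD complement sets of
both tails, tolerance 0.2 kcal/mol), so it serves as a dependency-free
fallback and as an independent cross-check, never as a second copy of the
same computation.

**Usage vs affinity.** Usage counts of the 4–8 nt SDs complementary to the
extended core are regressed on ΔG by ordinary least squares with
intercept, linear and quadratic terms — the minimal model that can exhibit
the reported *interior* optimum ("intermediate affinity preferred").
Reported: R², the regression F-test p-value, and the fitted optimum
−b₁/(2b₂) when curvature is negative. The HEG/LEG contrast reports
per-SD usage proportions by class, each class's |quadratic coefficient|
(peak sharpness) and R², and the SD with the largest HEG-minus-LEG
proportion difference. Usage counts are raw match counts, not per-gene
normalised.

## Expression classes

Genes with zero or missing protein abundance are excluded; the rest are
ranked descending and the top and bottom floor(0.10·n) become HEG and LEG.
Boundary ties are resolved by lexicographic gene id and logged. Classes
are invariant under monotone transforms of abundance. Mapping of external
protein ids to annotation gene ids is out of scope; input must already be
keyed consistently.

## Synthetic data: what it emulates, and what it does not

The generator produces all inputs with controlled truth, each stage from
its own labelled substream of a master seed (byte-identical reruns):

* **Reads** (default 20,000 × 51 nt, matching the emulated experiments'
  read length): windows of a synthetic rDNA 3' region ending at a terminus
  drawn from a mixture (default 60%/25%/15% at +5/+3/+0 relative to the
  CCUCC core — a dominant long form with shorter nibbled forms), with
  i.i.d. substitution errors at 1% and a 10% admixture of interior decoy
  windows that the retention filter must remove. The reference's 3'
  portion is the known mature tail plus a short genomic extension; its 5'
  filler is random sequence (the real annotated rDNA is not shipped — the
  construct is synthetic and labelled as such).
* **Genome** (default 300 genes): random-strand CDSs whose 30-nt upstream
  windows contain exactly the planted SD (drawn from a pool of tail
  complements, default centred on GGAGG/AGGAGG variants) at a spacer
  drawn from a distribution centred on 7 nt; backgrounds are resampled to
  suppress spurious ≥4-nt complements, and residual failures are recorded
  in the truth table rather than silently accepted. 20% of genes are
  SD-less.
* **Abundance**: log-normal (σ = 1) with an optional multiplicative boost
  for designated SD classes, enriching the top decile for them; 10% of
  genes get zero abundance.

Not emulated: realistic rRNA:mRNA read ratios, indel errors, coverage and
composition biases, operon structure, mRNA secondary structure around the
initiation region, and real genomes' dense spurious SD-like matches.
Passing the recovery tests therefore shows the *machinery* is correct
(alignment, filtering, counting, the statistic, the inference rules), not
that the biological conclusions would reproduce on any particular genome.

## Numerical and calibration choices

* Tolerances: the expected-usage statistic is exact up to float round-off
  and is tested against a rational-arithmetic enumeration at 1e−12;
  duplex reference energies are asserted within ±0.1 kcal/mol; the
  internal/external engine agreement within 0.2 kcal/mol.
* Terminus-mixture recovery is judged against the filter-conditional
  expectation w_k ∝ π_k (1 − e)^(5 + k): a read ending k nt past the motif
  survives the error-free-3'-zone rule with probability (1 − e)^(5 + k),
  so the retained composition differs deterministically from the planted
  π by up to ~0.8 pp at e = 1% — the correct null for an unbiased
  pipeline, computed in closed form independently of the implementation.
  The interval is the 99% binomial CI at the retained depth.
* Degenerate inputs raise: empty terminus distributions, tails without
  CCUCC or outside 10–20 nt, unpairable strand pairs, all-equal ΔG
  designs, empty abundance tables, site-usage tables with no favored site.
* Problem sizes were chosen so the whole suite runs in well under a
  minute: 20,000 reads for terminus recovery, 200–300 genes for geometry
  and core recovery (the core-footprint recovery needs ≥200 genes for the
  weakest-site ratio to clear 1 reliably).

## Known limitations

* The aligner is substitution-only; indels near the 3' end would shift
  the apparent terminus rather than being absorbed.
* Upstream windows wrapping a circular-origin boundary are rejected, and
  upstream regions overlapping a neighbouring CDS are still scanned (no
  operon logic), mirroring the analysed workflow.
* The quadratic usage-vs-ΔG model is descriptive; with few distinct SD
  sequences the F-test has little power, and genome-scale R²/p values
  require the real genomes and abundance tables, which this package does
  not download.
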