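# Methods

This note records the models, parameter choices and numerical decisions
behind `endomir`, and what the simulation-based tests do and do not
demonstrate.

## The synthetic experiment

The generator emulates a 12-library design: two reciprocal crosses
(B73 × Mo17 and Mo17 × B73, maternal parent first) sampled as whole
kernels at 0, 3 and 5 DAP and dissected endosperm at 7, 10 and 15 DAP.
Defaults were chosen once as the study conditions and are not tuned:

- **Precursors.** `design_hairpin` builds a perfect-complement stem:
  5-nt pad, the 21-nt mature, a 4-nt spacer, optionally a loop-proximal
  tandem duplex, a terminal loop, then the reverse complement. The star
  is the pairing partner of the mature shifted for the canonical 2-nt
  3′ overhangs on both duplex ends. The loop is drawn from {A, C} only:
  A and C cannot pair with each other or themselves (even allowing
  G:U), so the loop stays unpaired by construction and the designed
  stem is a maximum-pairing structure. Default mature sequences are the
  18 published novel endosperm miRNAs; extra hairpins recycle them with
  substitutions, and tandem duplexes are interior-reversed variants so
  every planted sequence is unique.
- **Abundance.** Intended expression is specified in RPM per
  (cross, stage). The canned truth set cycles four trajectory
  archetypes over 7/10/15 DAP with 4-fold steps at a base of 400 RPM,
  kernels flat at 8 RPM (strong endosperm enrichment), and a mild
  0.8× reciprocal-cross asymmetry. Star reads default to 10% of the
  mature, tandem duplexes to 50%.
- **Counting model.** Per library, planted reads are one multinomial
  draw across all planted species proportional to intended RPM; there
  is no PCR-duplication or sequencing-error model because the analysis
  operates on collapsed tags. When `background_fraction` is `None` the
  background fills exactly to the library total, making intended RPM
  unbiased in expectation (this is what makes "recovered RPM within 3
  multinomial SD of intended" a well-posed check); an explicit fraction
  is honoured verbatim.
- **Background.** 24-nt-dominated length mix (68% 24-nt, 12.5% 21-nt,
  the rest spread over 20–25), uniform base composition except a forced
  46% 5′-A frequency at 24 nt — the composition statistics downstream
  tests assert, not realistic sequence content. Background reads are
  random, so they essentially never collide with a precursor; real
  genomic repeats and degradation products are *not* modelled, which is
  why simulated annotation precision (~100%) is an upper bound, not a
  field estimate.
- **Alleles.** A truth record may carry a SNP (1-based offset within
  the mature; allele A = B73 by convention). Endosperm libraries draw
  allele A per read at the maternal dosage (2/3 when B73 is maternal,
  1/3 otherwise); kernels use 1/2 since the maternal sporophyte and
  filial mix is not resolved. A genotype-bias override
  (`allele_a_fraction`) plants the same allele-A fraction in both cross
  directions.
- Reads are 3′-adapter-ligated (TruSeq small-RNA adapter by default),
  FASTQ qualities are constant `I`, and identical config + seed gives
  byte-identical files (per-library RNG streams seeded from
  `[seed, library_index]`).

## Preprocessing

Adapter trimming takes the sequence 5′ of the left-most full adapter
occurrence, falling back to a ≥ 5-nt adapter prefix at the read 3′ end,
and iterates to a fixed point so trimming is idempotent. Matching is
exact: error-tolerant trimming is unnecessary at these scales and the
tolerances are configurable. Untrimmed reads are kept (collapsing
leaves spurious tags at negligible counts). Reads outside 15–30 nt are
discarded; survivors collapse to unique tags with per-library counts,
the atomic unit everywhere downstream. The RPM denominator is the
per-library retained-read total (not genome-mapped reads) — the
conservative reading when the source of the total is ambiguous — and is
configurable.

## Folding and duplex evaluation

Folding maximizes base-pair count (Watson–Crick + G:U) over nested
structures with a minimum hairpin loop of 3, via the interval dynamic
program with a numpy-vectorized split maximization. Pair count stands
in for free energy: it is deterministic, parameter-free, and exact on
designed stems; a thermodynamic backend could be slotted in but
minimum-free-energy evaluation is out of scope. Ties are broken by
pairing the 5′-most base with its most distal admissible partner, which
reconstructs the outer stem of a hairpin rather than an equal-count
rearrangement. Tests compare against an exhaustive enumerator of all
nested structures (exponential; used at ≤ 22 nt only).

A mature placement is accepted as a duplex iff: it does not span the
terminal loop, ≤ 4 mature positions are unpaired, no asymmetric bulge
exceeds 2 nt, and the star region — read off the pairing by linear
extrapolation to the mature termini plus the 2-nt 3′ overhang on both
ends — lies inside the window and clear of the mature. These tolerances
are the community plant-miRNA annotation criteria; all are arguments.
Star read support is recorded but never required, since requiring it
was not stated for the original calls.

The high-confidence filter is a pure predicate: length 21, 5′ base U,
and RPM strictly above 100 in at least one library. The "at least one"
reading was chosen over "in all 12" because novel endosperm miRNAs are
near zero in kernels, which an all-12 reading would exclude; the
threshold count is configurable (k-of-n).

Tandem detection ranks accepted non-overlapping duplexes on one hairpin
by distance to the loop midpoint (center of the innermost pair): the
distal duplex keeps the base name, proximal ones get `.1`. Overlapping
placements are merged beforehand, keeping the most abundant tag, and a
read stack landing on an accepted duplex's star arm is folded into that
duplex rather than double-called.

## Temporal patterns and enrichment

Stage values at 7/10/15 DAP (reciprocal crosses combined by summing)
yield two steps; a step is up if `(y + 1)/(x + 1) ≥ 1.5`, down if
≤ 1/1.5, else level. One sustained direction → one-step-up/down;
opposite directions → two-step-up-down / down-up; two level steps →
flat. The flat class is an addition: the four named classes cannot
partition profile space without it. The 1.5-fold threshold and 1.0 RPM
pseudocount are defaults exposed in the API; with pseudocount 0 the
classification is exactly scale-invariant. Endosperm enrichment is
`(endosperm mean + ε)/(kernel mean + ε)` with ε = 0.1 RPM.

miRNA–target correlation pools stage-matched (miRNA RPM, target FPKM)
pairs over predicted interactions, drops targets never reaching
1 FPKM, and reports Pearson r with the two-sided t-transform p
(n − 2 df). Both pooled-stage and per-gene-mean modes exist because the
aggregation used for the published figure is ambiguous; pooled is the
default.

## Allele bias

Reads placing on a mature locus are partitioned by their base at the
SNP offset (scan with the SNP position wildcarded, so both alleles and
third-base reads place); third bases and non-covering reads are
ambiguous and excluded from testing, not split. Each endosperm library
gets a 1-df χ² goodness-of-fit against the expected allele-A fraction:
2/3 when allele A is maternal in that cross, 1/3 otherwise (the
biologically correct triploid null), with an optional 1:1 null since
the original test's null is unstated. Benjamini–Hochberg adjustment is
applied across the per-library tests (raw p is also emitted). The class
logic: the same allele significantly over-represented in both cross
directions → genotype bias; the significant excess tracking the
maternal (paternal) parent → parent-of-origin; otherwise unbiased. The
exact type-I rate of this discrete test at n = 200, α = 0.01 under the
2:1 null is 0.0107 — close to nominal, which the calibration test
checks empirically. The CAPS enzyme's recognition site is a required
argument: the name printed for the original assay does not match
standard nomenclature, so no constant is safe to bake in.

## Target scoring

Allen-style penalties: mismatch 1.0, G:U 0.5, single-nucleotide bulge
2.0, doubled over miRNA positions 2–13; expectation cutoff 3.0.
Positions 10–11 (the cleavage-directing positions) are doubly penalized
but not forbidden. This is a re-implementation of the published scoring
family, not a byte-identical clone of any server; translation-
inhibition classification (central bulge) is out of scope and all hits
are reported as cleavage-type with the cleavage position opposite
miRNA positions 10–11.

## Problem sizes and determinism

The test suite and acceptance script run the full pipeline at 10–50 k
reads per library and use 200-sequence folding oracles, 10 000-rep χ²
calibration, 200-rep power runs, 500-profile pattern recovery and 5-kb
target scans — sizes at which every stochastic check has comfortable
margins while the whole suite stays fast. Every stochastic step takes
an explicit seed; spec-level invariants (conservation of reads, RPM
totals, fragment lengths) are asserted as exact.

## Known limitations

- Base-pair maximization can misfold precursors whose true structure
  depends on stacking energies; fine for designed stems and screening,
  not for publication-grade structure figures.
- Exact-match mapping and trimming: no sequencing-error tolerance.
- Multi-mapping tags contribute full counts to every matched locus.
- The background model carries no genomic structure, so simulated
  precision/recall bound, rather than estimate, performance on real
  libraries.
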