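# Methods

This note documents the models, conventions and numerical choices behind
`rpoaprof`, in the order the pipeline uses them.

## Marker, taxonomy and primers

The package targets the single-copy *rpoA* gene, whose inter-species
divergence within *Faecalibacterium* supports species-level resolution where
16S rRNA does not.  Human-origin *Faecalibacterium* is modelled as twelve
species-level phylogroups ("Group 1" … "Group 12"); the bundled taxonomy
table maps each group to its species name (or "Not classified yet") and a
type/representative strain.

The shipped primer pair (meta-rpoA-F `CACCCCBGTKCTCAAGGTGAA`, meta-rpoA-R
`CCSARRTTRCGRACYTTCATC`) amplifies a 325-bp fragment.  Amplicon length is
defined **primer-inclusive** throughout (21 + 283 + 21 bp); this is a
package convention, since the literature value does not state whether primer
annealing sites are counted.

Primer design from a multiple alignment uses per-column minimal IUPAC
consensus codes.  A base enters a column's code only if its frequency is at
least `min_base_freq` (default 0.05) — rare alleles, which at amplicon scale
are indistinguishable from sequencing error, would otherwise inflate
degeneracy.  Candidate windows must satisfy a degeneracy cap (default 64,
the degeneracy of the shipped reverse primer) and match all but
`max_missed_targets` rows with zero mismatches; pairs are ranked by
(coverage desc, product of degeneracies asc, product length desc, leftmost
forward start), a total order that makes the output deterministic and
invariant to row order.  Product length is measured in alignment columns;
for gapless alignments (all bundled fixtures) this equals sequence length.

In-silico PCR matches degenerate primers against concrete templates through
base-set membership (never code-vs-code intersection), allows
`max_mismatch` mismatches (default 3) but none within `protect_3prime`
(default 3) bases of each primer's 3' end — the extension-blocking end of a
real PCR — and scans both strands.  Products found on the reverse strand
are reported in product orientation with coordinates mapped to the
template's forward strand.  Design-time coverage counting uses 0 mismatches;
screening uses the 3/3 defaults.

### Copy-number arithmetic

For a plasmid construct of mass *m* and total length *L*,
`copies = m · N_A / (L · 650 g mol⁻¹ bp⁻¹)` with the exact SI Avogadro
constant; 650 g mol⁻¹ bp⁻¹ is the standard mean dsDNA base-pair mass.  The
default construct geometry is a 2,450-bp vector plus a 990-bp *rpoA* insert
(3,440 bp total): the vendor's exact backbone length is not public, and this
geometry is the documented assumption under which 100 pg equals
7.43 log₁₀ copies.

## Pairwise identity

Classification hinges on one number, the percent identity between an ASV and
a reference amplicon, so its definition is fixed precisely:

* global alignment with free terminal gaps on both sequences
  (match +1, mismatch −1, gap −2, linear gap cost);
* identity = 100 · matches / aligned columns, where aligned columns exclude
  the terminal-gap runs and **include** internal gap columns (conservative:
  an internal indel always costs identity);
* among co-optimal alignments, the one with the fewest counted columns and
  then the most matches is canonical.  This tie order makes the ungapped
  alignment canonical for substitution-only divergence, so a variant with
  *k* substitutions in an *L*-mer scores exactly 100·(L−k)/L, and a read
  that is an exact substring of a reference scores exactly 100;
* the ambiguity letter N in a read matches nothing (it encodes a low-quality
  base, not a wildcard);
* a degenerate alignment whose aligned core is empty reports identity 0.

The aligner is a numba-compiled dynamic program over
(score, −columns, matches).  The test suite checks it against a pure-Python
tuple DP and, for tiny inputs, against brute-force enumeration of every
end-gap-free alignment, and independently against Biopython's pairwise
aligner under the same scoring.

## Reference library

Reference FASTA headers follow `>Group{n}|{species}|{strain}`; group ids
outside 1–12 and duplicate ids are errors.  Classification compares ASVs to
the **amplicon region** of each reference (extracted by in-silico PCR), not
the full gene — reads never cover more than the amplified fragment, and
full-gene comparisons would be dominated by terminal gaps.  References that
yield no product are flagged and excluded rather than fatal, mirroring real
libraries that contain partial genes.

Library QC (`validate_separation`) computes all-pairs amplicon identity and
flags cross-group pairs above 94 % and within-group pairs below 98 %.  The
94 % ceiling is applied to *inter*-group comparisons: the source literature's
phrasing ("among intra-species comparisons") appears to be a slip, since a
94 % ceiling within a species would contradict the ≥ 98 % assignment tier.

## Profiling pipeline

Thresholds (all inclusive on the retained side, exactly as printed in the
protocol they implement):

| parameter | default | meaning |
|---|---|---|
| `trim_3prime` | 23 nt | index-tail trim at each read's 3' end |
| `min_asv_len` | 250 bp | minimum retained ASV length |
| `min_sample_reads` | 10,000 | minimum retained reads per sample |
| `genus_min_relab` | 1 % | 16S genus-level inclusion floor |
| `kcal_range` | 600–4000 kcal/d | dietary-outlier exclusion |
| `detection_relab` | 0.5 % | detection threshold for prevalence and richness |
| `minor_median` / `minor_prevalence` | 1 % / 10 % | minor-label rule |
| `group_identity` / `genus_identity` | 98 % / 95 % | classification tiers |

**ASV surrogate.**  Error-model denoising (DADA2) is out of scope; ASVs are
produced by exact dereplication across samples with singleton removal
(total count 1).  Externally denoised ASV FASTA + count tables are accepted
through `asvs_from_table`.  The surrogate's known accuracy limit: reads whose
error variant occurs only once are lost, so at 50,000 reads and 0.1 %
per-base error ~5 % of reads are dropped, slightly more for low-abundance
templates (singleton-variant retention is 1−e^(−λ) with λ the expected
variant multiplicity).  End-to-end, recovered 5-species compositions deviate
from truth by a mean L1 of ≈ 0.017 under those conditions — adequate for
composition work, and the reason the composition-recovery check is stated on
the mean over ten seeded communities rather than per community.

**Classification.**  Best-identity search over the library with the tier
rule above.  A cross-group tie at ≥ 98 % is resolved to the earliest library
record and flagged (`tie_flag`), keeping results independent of hash order.
Two implementation paths exist with identical semantics: a vectorized
Hamming fast path for ASVs whose length equals the library's common
amplicon/core length and whose best distance is ≤ 6 (in that near-identical
regime the anchored ungapped alignment is optimal, so identity is exactly
(L−h)/L), and the general aligner behind an edlib candidate screen
(references within `screen_margin` = 5 of the minimum infix edit distance;
`exhaustive=True` disables screening).  Path equivalence is asserted in the
test suite.

**Composition.**  Per-sample relative abundance uses all retained reads as
the denominator, including the "Other Faecalibacterium" and "Others" bins —
with genus-specific primers that is the natural whole.  Species richness
applies the same ≥ 0.5 % detection rule as prevalence (stated in the source
only for prevalence; adopted for consistency).

**Cohort cascade.**  Exclusions run in fixed order — 16S genus abundance
< 1 %, cancer history, kcal outside range, < 10,000 reads — and a sample is
counted only at the first stage it trips, which reproduces staged cascade
arithmetic (660 enrolled − 55 − 13 − 3 − 9 = 580) even when criteria
overlap.

## Statistics

* **Mann-Whitney U**: exact null distribution (Gaussian-binomial recurrence)
  for pooled n ≤ 16 without ties, two-sided p = 2·min(P(U≤u), P(U≥u))
  capped at 1; otherwise the tie- and continuity-corrected normal
  approximation (scipy).  Fewer than three groups routed here from
  Kruskal-Wallis.
* **Kruskal-Wallis** with tie correction (scipy), pairwise Mann-Whitney
  follow-ups Bonferroni-adjusted by C(k,2).
* **Bray-Curtis** via scipy; an all-zero pair is defined as distance 0 with
  a warning.
* **PCoA**: Gower double-centering + symmetric eigendecomposition;
  coordinates only for positive eigenvalues (relative tolerance 1e-12);
  negative eigenvalues reported, uncorrected (the vegan-default behaviour);
  percent variance over positive eigenvalues; deterministic sign convention
  (largest-magnitude loading positive per axis).
* **PAM**: classic BUILD + steepest-descent SWAP, ties to the lowest index —
  fully deterministic without a seed; k chosen by average silhouette width
  (scikit-learn, precomputed distances), ties to the smaller k.  Degenerate
  input (all points identical) is an error, not a silent answer.
* **envfit**: least-squares fit of each (centred) variable on the first two
  ordination axes — the plotted space — with R² the explained variance
  fraction and p from seeded permutations of the variable.
* **PERMANOVA**: pseudo-F from the total/within sum-of-squared-distances
  partition; seeded label permutations.
* All permutation p-values use the add-one estimator
  (1 + #{perm ≥ obs})/(n_perm + 1); the default permutation count is 999 and
  seeds are explicit arguments, never wall-clock.  Results are bit-exact
  reproducible under a fixed seed.
* **Associations**: per feature × exposure, ordinary least squares of
  log2(relative abundance + half-minimum pseudocount) on the exposure plus
  covariates (default BMI, age, sex; categorical covariates enter as
  factors).  This mirrors a MaAsLin2-default linear model with TSS
  normalisation, half-minimum pseudocount and LOG transform; MaAsLin2's
  variance filtering and random effects are deliberately omitted (a
  single-timepoint cohort needs no random effects).  BH FDR runs across all
  feature × exposure tests; confidence tiers are q < 0.1 (high), < 0.25
  (moderate), < 0.3 (exploratory).  Features default to non-minor labels —
  median ≥ 1 % **and** prevalence ≥ 10 % — matching the minor-species rule
  used for reporting.  Exposures collinear with the covariates are dropped
  with a warning.

## Synthetic data

The generators produce the structure the method assumes, with every artifact
traceable to a truth manifest:

* **Library**: one random 283-bp ancestral core; group *g* mutates its own
  disjoint block of ⌈8 % · 283⌉ positions (divergence cannot collapse by
  chance: any two groups differ at ≥ 2 blocks minus strain noise, keeping
  cross-group amplicon identity ≤ ~88 % < 94 %); strain variants add at most
  ⌊1 % · 283⌋ further substitutions (within-group identity ≥ 98.7 %).
  Primer sites are concrete expansions of the degenerate primers, fixed per
  group so that site variation cannot erode within-group identity.  Default
  size: 106 records over 12 groups (9,9,…,8,8).
* **Reads**: merged single-end amplicons (paired-end merging is out of
  scope).  A mock sample carries **one** (seeded) strain per species — how
  physical mock communities are assembled — with a uniform strain mixture
  available via `strain_mixture=True`.  Errors are independent per-base
  substitutions (default 0.1 %); no indels by default, keeping identity
  arithmetic analytic (the aligner's indel handling is stressed separately
  in unit tests).  A random 23-nt tail is appended so preprocessing has
  something to trim.
* **Cohort**: 660 subjects with age, sex (≈ 107:473 M:F), BMI, caloric
  intake, defecation-frequency class, exercise habit, region, 16S genus
  abundance, 18 dietary-category and 7 nutrient intakes (log-normal);
  the four exclusion categories are assigned to disjoint subjects at
  configurable counts (default 55/13/3/9).  Species compositions are
  Dirichlet draws whose mean mirrors the cohort structure the method was
  built for (Groups 3 and 4 dominant; Groups 1, 6, 11 intermediate; the
  rest minor).  Injected exposure effects multiply a label's fraction by
  exp(β·z) (z the standardised exposure) before renormalisation, with β
  recorded in the manifest.

All generators are pure functions of (config, seed).

What passing tests on these fixtures do **not** show: robustness to indel
sequencing errors, chimeras, paired-end merging artifacts, host/PhiX
contamination, primer-coverage bias across real strain diversity, or
compositional effects of real cohorts.  The cohort-scale findings of the
study this method comes from depend on its deposited reads and are not
reproduced here; what is validated is the estimator (parameter recovery on
synthetic cohorts of the same size).

## Problem sizes

The test suite and `scripts/acceptance.py` use: 10 mock communities of
50,000 reads at 0.1 % error for composition recovery; 500-replicate nulls
(99 permutations each) for PERMANOVA/envfit calibration at n = 30; all
2,018 two-group splits of pooled n ≤ 10 for the exact Mann-Whitney check;
200 cohorts of n = 580 for injected-effect sign recovery; 50
planted-mutation ASVs for the tier boundaries.  These sizes keep each
property at the scale it is stated for while the whole suite runs in a few
minutes on one CPU.

## Known limitations

* The ASV surrogate loses singleton error variants (bias quantified above);
  use externally denoised tables for real data.
* Identity is defined by one fixed scoring scheme; closed-reference tools
  with different gap conventions can differ near tier boundaries.
* Product length in `design_primer_pairs` is measured in alignment columns,
  an approximation for gapped alignments.
* The Hamming fast path assumes a library with a uniform amplicon length;
  mixed-length libraries silently take the slower exact path.
* envfit is restricted to the first two axes (the plotted space);
  PCoA applies no negative-eigenvalue correction.
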