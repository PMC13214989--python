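# rpoaprof

Species-level profiling of *Faecalibacterium* from *rpoA* amplicon sequencing.

*Faecalibacterium* is one of the dominant butyrate-producing genera of the
human gut, and it is no longer one species: human-origin strains fall into
twelve species-level phylogroups (including *F. prausnitzii*, *F. longum*,
*F. taiwanense*, *F. duncaniae* and several yet-unclassified groups).  16S
rRNA sequencing cannot separate them, and species-specific qPCR does not
scale to cohorts.  This package implements a targeted-sequencing alternative
built on the single-copy *rpoA* gene: genus-specific degenerate primers
amplify a 325-bp *rpoA* fragment, amplicon sequence variants (ASVs) are
classified against a curated 12-group reference library by percent identity,
and per-sample species compositions are joined to host metadata for
association analysis.  It is aimed at microbiome researchers who want
species-level *Faecalibacterium* profiles from amplicon data — and at anyone
who wants to test such a pipeline end to end without touching real reads:
every component is exercised on synthetic mock communities with known truth.

## The method

**Primers.** The shipped genus-specific pair is

```
meta-rpoA-F  5'-CACCCCBGTKCTCAAGGTGAA-3'   (6 concrete variants)
meta-rpoA-R  5'-CCSARRTTRCGRACYTTCATC-3'   (64 concrete variants)
```

IUPAC degenerate bases (B = C/G/T, K = G/T, ...) broaden coverage across the
genus.  `primers.design_primer_pairs` re-derives such pairs from a multiple
alignment (consensus windows under a degeneracy cap), and
`primers.in_silico_pcr` predicts products on both strands with 3'-protected
degenerate matching.  The copy-number arithmetic used when validating primers
against synthetic plasmid constructs is

```
copies = m · N_A / (L · 650 g mol⁻¹ bp⁻¹),
```

so 100 pg of the default 3,440-bp construct is 10^7.43 ≈ 2.7·10⁷ gene copies.

**Classification.** Each ASV is assigned by its best end-gap-free percent
identity *s* against the amplicon regions of the reference library:

- *s* ≥ 98 %  → the species group of the best reference (Group 1–12),
- 95 % ≤ *s* < 98 %  → "Other Faecalibacterium",
- *s* < 95 %  → "Others".

The library separation this relies on (inter-group identity < 94 %,
intra-group ≥ 98 %) is checked by `reference.validate_separation`.

**Pipeline.** Reads are 3'-trimmed by 23 nt (index tails), primer-stripped,
length-filtered (≥ 250 bp), dereplicated into ASVs (singletons discarded),
classified, and turned into per-sample relative abundances (samples with
< 10,000 reads dropped).  Cohorts pass a fixed exclusion cascade (genus
abundance < 1 % by 16S, cancer history, caloric intake outside
600–4000 kcal/day, < 10,000 reads).  The statistics layer provides
Mann-Whitney/Kruskal-Wallis tests with Bonferroni-adjusted pairwise
comparisons, Bray-Curtis PCoA, PAM clustering with silhouette-selected *k*,
envfit-style vector fitting, PERMANOVA, and multivariable linear
diet/nutrient associations with Benjamini-Hochberg FDR (confidence tiers
q < 0.1 / 0.25 / 0.3).

## Worked example

Profile a 50,000-read mock community with a known 4-species composition:

```python
from rpoaprof.primers import default_primer_pair
from rpoaprof.profiling import (build_profiles, call_asvs, classify_asvs,
                                preprocess_reads)
from rpoaprof.synthetic import (SimConfig, simulate_reference_library,
                                simulate_sample_reads)

cfg = SimConfig(seed=42, reads_per_sample=50_000)
library, _ = simulate_reference_library(cfg)
composition = {"Group 3": 0.40, "Group 4": 0.30, "Group 6": 0.15, "Group 11": 0.15}
batch, _ = simulate_sample_reads(library, composition, cfg)

pair = default_primer_pair()
clean, pstats = preprocess_reads(batch, pair)
asvs = call_asvs([clean])
classifications = classify_asvs(asvs, library, pair=pair)
profiles, _ = build_profiles(asvs, classifications)

print(f"reads kept after trimming: {pstats.n_kept}/{pstats.n_input}")
print(f"ASVs called: {len(asvs)}")
p = profiles[0]
print(f"retained reads: {p.total_reads}")
for label, frac in sorted(p.rel_abundance.items(), key=lambda kv: -kv[1])[:4]:
    print(f"{label:<10s} {100 * frac:6.2f} %")
```

prints

```
reads kept after trimming: 50000/50000
ASVs called: 2533
retained reads: 47749
Group 3     40.05 %
Group 4     30.37 %
Group 11    14.89 %
Group 6     14.69 %
```

The recovered abundances sit within ~0.5 percentage points of the seeded
truth (40/30/15/15); the 2,533 ASVs are mostly sequencing-error variants of
the four true templates, correctly absorbed by the ≥ 98 % identity tier.
~2,300 of the 50,000 reads were lost as singleton error variants, which is
the documented accuracy limit of the dereplication-based ASV surrogate (see
`docs/methods.md`).

The same pipeline is available from the shell:

```bash
rpoaprof simulate --out-dir data --seed 7 --n-samples 2
rpoaprof build-ref data/reference.fasta --out-prefix ref
rpoaprof profile data/S0001.fasta data/S0002.fasta \
    --library data/reference.fasta --out-prefix run
rpoaprof stats run.composition.tsv data/metadata.tsv \
    --out-prefix stats --exposure RICE --exposure MILK --seed 7
```

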