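# Methods

`symbiorate` estimates how fast a bacterial endosymbiont genome changes
when two samples of the same lineage, separated by a known number of
years, are compared — and quantifies the genome degradation that
accompanies host restriction (pseudogenization, coding-density loss,
rearrangement, prophage decay). This note documents the models, the
numeric choices, and what the synthetic data do and do not emulate.

## The rate estimator

For one comparison (an isolate against a reference of known temporal
separation) the substitution rate is the raw ratio

```
r = k / L / t
```

- `k` — substituted bases observed at third codon positions of retained
  CDSs. SNPs count one; equal-length MNP/complex records are decomposed
  base by base; indels and length-changing records contribute nothing,
  because a per-site change count is only defined for substitutions.
- `L` — the number of *considered* third-position sites: third positions
  of retained CDSs, by default intersected with the coverage mask (a
  `denominator="all-third"` option counts every third position of
  retained CDSs instead; with full coverage the two coincide).
- `t` — elapsed years, supplied per comparison. For lineages that split
  before sampling, the natural choice is the sum of both branch lengths
  since the split; the configuration takes `t` explicitly rather than
  guessing.

Third positions are used because most changes there are synonymous, so
the count approximates the neutral accumulation process without fitting
a codon model. No multiple-hit correction is applied: over year-to-
century intervals the expected hits per site are ≤ 1e-4 and the raw
count is unbiased to first order. Back mutations at longer time scales
make this an underestimate — a known property of the estimator, not a
bug.

### Site and variant filters

Positions enter the analysis only when every sequencing library covers
them at `min_depth` (default 5×). Per-library boolean masks are
intersected; a CDS is retained only if *entirely* covered (one uncovered
base disqualifies it); a variant is retained only if every reference
base it spans is covered. Raising `min_depth` therefore can only shrink
the mask, the retained-CDS set, `k`, and `L` — a monotonicity the test
suite asserts.

The codon-position map labels every position 1/2/3 within its owning
CDS, cycling from `start+phase` on the plus strand and from `end-phase`
downward on the minus strand. Positions claimed by two or more CDSs are
ambiguous and excluded from numerator and denominator alike. CDSs whose
length minus phase is not a multiple of 3 have no defined frame (they
are typically pseudogenes) and are excluded with a log message.

### Effects and spectrum

Variant effects are classified under a configurable genetic code,
default translation table 4 (Mollicutes/Spiroplasma: TGA = Trp).
Substitutions confined to one codon are compared on the whole-codon
amino-acid change; indels in CDSs are frameshift when the net length
change is not a multiple of 3, else in-frame; everything that spans
codon or CDS boundaries is reported as `complex` rather than guessed.

The substitution spectrum collapses the twelve directed single-base
changes into six strand-symmetric classes (G→A and C→T are both GC→AT,
etc.); `gc_to_at_fraction` is the GC→AT share, reported as undefined
when no substitutions were classified. In reduced AT-rich endosymbiont
genomes this fraction is expected to dominate, reflecting the universal
deamination-driven GC→AT pressure unopposed by mismatch repair.

## Degradation metrics

- **Truncation rule.** Within each orthogroup shared by the two strains,
  each strain's longest member is compared with the other strain's
  longest; a strain is flagged when the ratio is ≤ 0.60 (boundary
  inclusive: exactly 60 % flags). "Longest member" is the conservative
  reading when a strain has paralogs.
- **Coding density.** 100 × |union of CDS intervals| / genome length;
  overlapping CDSs count once.
- **Prophage rule.** A gene is prophage-related when some hit against a
  viral-protein set is ≥ 60 % identical over ≥ 50 % of the viral
  protein's length; the best hit is the highest-bitscore passing hit.
- **Synteny blocks.** From whole-genome alignment hits (query = genome
  A): drop hits < 1000 bp or < 95 % identity (boundaries kept: exactly
  1000 bp and exactly 95 % pass), then keep hits greedily in descending
  bitscore order (ties: longer alignment, then subject coordinates),
  retaining a hit only if its A-interval overlaps no previously retained
  one — one best match per A region, with retained A-intervals provably
  disjoint. Per block, CDS density per kb is counted by CDS *midpoint*
  to avoid double-counting genes that straddle block edges. The summary
  partitions blocks by the sign of the A−B CDS-count difference, with
  base-pair spans measured on A.
- **Divergence time.** `t = d / (2r)` for per-site divergence `d` and
  clock rate `r`, assuming both lineages accumulate changes
  independently; `d-over-r` (single accumulating lineage, an upper
  bound) is available as a flag. The divergence measure is an explicit
  argument — all-site and third-position divergences are both
  legitimate inputs, and the choice is the caller's.

## The synthetic generator

The generator produces the statistical structure the analyses assume,
with exact ground truth, so every stage is verifiable without external
data:

- **Genome.** I.i.d. nucleotides at a target GC (default 0.27 — AT-rich,
  as in reduced endosymbiont genomes), with `n_cds` non-overlapping
  CDSs of in-frame lengths placed with random gaps and strands. Defaults
  (1 Mbp, 800 CDSs of 300–1500 bp) give ~72 % coding density, between
  the degraded (~65 %) and intact (~82 %) ends of the comparison the
  package targets. CDSs are coordinate frames, not ORFs: start/stop
  codon structure is irrelevant to every consumer and is not imposed.
- **Evolution.** Single-hit: each site mutates at most once per
  comparison, valid while `rate × years ≪ 1` (≤ 1e-4 in all regimes
  simulated here). The class of each change is drawn from the
  six-class spectrum conditioned on the reference base; per-site
  probabilities are weighted by (compatible-class weight / base-group
  composition), which makes the realized marginal class distribution
  equal the configured weights exactly while keeping the aggregate
  per-site rate at the configured value. Positions 1 and 2 mutate at
  half the third-position rate by default (purifying selection);
  noncoding positions at the full rate. The simulator records every
  change and its own synonymous/nonsynonymous bookkeeping, computed
  through a separate code path from the pipeline classifier so the two
  can be cross-checked.
- **Depth.** Per library, per position Poisson(`mean_depth`), with
  contiguous dropout segments forced to zero. Dropout is segmental, not
  i.i.d., precisely to exercise the entirely-covered-CDS filter the way
  real coverage holes do. Note that i.i.d. Poisson depth is *harsher*
  than real autocorrelated coverage for the "entirely covered at
  `min_depth`" rule: at mean depth 20, random dips below 5× are rare,
  but thresholds near the mean reject almost every CDS.
- **Rearrangements.** `n` random non-overlapping interior segments
  partition genome A into `2n+1` fragments; inverted segments are
  reverse-complemented in place, translocated segments reinserted at a
  random other junction. Every fragment boundary is a breakpoint, so the
  true syntenic blocks are exactly the fragments in B order; one
  alignment hit is emitted per true block. CDSs straddling breakpoints
  are dropped from B's annotation.
- **Orthogroup erosion.** One orthogroup per CDS; a random subset of
  strain-B copies keeps 20–55 % of the original length (flagged ground
  truth), the rest 80–100 %; a small fraction of B members is lost
  entirely.

All randomness flows from one seeded `numpy` generator in a fixed order
(genome → evolution → depth → rearrangement → orthogroups), so a config
plus seed determines every output byte, including file checksums in the
fixture manifest.

**What the generator does not emulate:** sequencing error, read-level
artifacts (mapping bias, duplicates), indel evolution, recombination,
selection beyond the crude position-1/2 rate scaling, compositional
heterogeneity along the genome, and real gene structure. Passing tests
therefore demonstrate that the *estimators and filters* are correct and
unbiased under the stated model — not that upstream variant calling on
real reads is error-free.

## Problem sizes and tolerances

The verification suite runs the backbone recovery at the study scale
(1 Mb, 800 CDSs, rate 1e-5/site/yr over 10 years, ~2.4 × 10⁵
third-position sites, so ~24 expected changes per replicate) across 100
replicate seeds, requiring the estimate within 3 Poisson standard errors
in ≥ 99 of them. Spectrum recovery uses 50 replicates on a 300 kb genome
and checks the pooled GC→AT fraction against the configured 0.60 inside
the 99 % normal sampling band. Synteny recovery uses a 500 kb pair with
5 inversions + 2 translocations and demands exact coordinate equality.
Numerical comparisons elsewhere are exact (integer counts) or at default
floating-point tolerance; there are no fitted tolerances.

## Design choices where the design was open

- Internal coordinates are 0-based half-open everywhere; 1-based
  conventions exist only at file boundaries.
- Multi-allelic VCF rows split per ALT; symbolic ALTs are skipped with a
  warning, not errors.
- Equal-length complex records are treated as MNPs (decomposed);
  length-changing complex records are counted in effect tallies but
  never in `k`.
- The greedy best-first block selection is one concrete realization of
  "a single best match per region"; it is deterministic, order-
  independent (total sort order with explicit tie-breaks), and easy to
  audit, which mattered more than optimality of total aligned length.
- `AnalysisConfig` defaults equal the standard thresholds (5×, table 4,
  0.60, 1000 bp, 95 %, 60 %/50 %) so that an empty config reproduces the
  canonical analysis.

## Known limitations

- No multiple-hit or back-mutation correction; rates over long
  intervals are underestimates.
- MNPs spanning codon boundaries are reported `complex`, not split into
  per-codon effects.
- The truncation rule compares lengths only; a full-length gene with
  internal stops is not flagged.
- Circular topology is recorded but coordinates are linear; features or
  blocks wrapping the origin are not supported.
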