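# Methods

## Problem and model

LINE-1 (L1) retrotransposons carry, besides their sense promoter, an
antisense promoter (ASP) in the first ~900 bp of the 5′ UTR with initiation
hotspots near +200 and +450. When the ASP fires, transcription exits the
element's 5′ end into flanking genomic sequence and produces an L1 chimeric
transcript (LCT): part L1 5′ UTR (antisense), part unique sequence. In
stranded paired-end RNA-seq such transcripts appear as read pairs with one
read matching an L1 5′ UTR antisense to the element and the mate anchored in
unique sequence nearby. `lctscape` detects these pairs, aggregates them into
loci, and characterises each locus (splice status, TSS region,
polyadenylation, genic context, group-level deregulation, promoter
methylation, CNV and chromatin environment).

Key modelling assumptions:

* **Gapless matching with a substitution budget.** The L1-side match is a
  contiguous, gapless alignment of ≥ `min_l1` bp (default 50) with at most
  `max_mm` substitutions (default 1, absorbing SNPs). Indels are not
  modelled; users with indel-rich data can substitute an external aligner
  and feed the finder a normalised alignment table.
* **Single-element assignment with an ambiguity guard.** Each read is
  assigned to the single best-matching element (longest match, then fewest
  mismatches, then lowest element id). When the runner-up hit on a
  *different* element is within `margin` bp (default 5) of the best length
  with no more mismatches, the read is discarded as unassignable — young
  subfamily copies are near-identical, and a chance 1–2 bp extension under
  the mismatch budget can otherwise flip the assignment and seed a spurious
  locus on a paralog within the 50 kb insert window. This mirrors the
  MapQ ≥ 30 uniqueness filter applied to long reads. A side effect is that
  the candidate set is no longer strictly monotone in `min_l1`/`max_mm` for
  contrived homology configurations; in practice (and in the property
  tests) monotonicity holds.
* **Locus geometry.** The unique side of an antisense chimera lies on the
  5′-exit side of the element. The R1–R2 distance is measured along
  transcription direction between the L1-side alignment end and the unique
  interval start; ≤ 0 means overlap or juxtaposition (continuous
  transcription), large positive values indicate splicing.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_l1` | 50 bp | minimum L1-side match length |
| `max_mm` | 1 | substitution budget of the L1-side match |
| `margin` | 5 bp | paralog-ambiguity guard on the best hit |
| `min_unique` | 30 bp | minimum repeat-free mate segment |
| `max_insert` | 50 000 bp | maximum genomic gap between the two sides, inclusive |
| `merge_gap` | 300 bp | cluster gap for unique intervals (≈ insert upper bound 280–340) |
| `g_cutoff` | 1.0 | deregulation threshold on Hedges' g (strict inequalities) |
| `min_mapq` | 30 | long-read mapping-quality filter |
| TSS windows | 0–500, 0–900 bp | ASP region / whole 5′ UTR, bounds inclusive |
| metaprofile | 1000/1000/1000 bp, 10 bp bins | flank / rescaled body / flank |

The splice classifier's constants (distance > 500; size > 1000 **and**
unique > 700; junction within ±200 bp of the L1 start; undetermined band
200–499 bp with 600–999 bp) encode the three-rule evidence scheme with
precedence spliced > undetermined > unspliced — any single rule suffices to
call a splice. The large-unique conjunct reflects that a > 700 bp unique arm
inside a > 1 kb locus can only arise from concatenating reads across a
removed intron. For a distance of 1–199 bp with size 600–999 bp the rules
are silent; such loci are called unspliced and flagged rather than guessed.

Sign convention for Hedges' g: **control minus tumor** over the pooled SD
with the small-sample factor J = 1 − 3/(4(n₁+n₂) − 9), so overexpression in
tumor gives g < 0 and `g < −cutoff` is reported as "up". g is computed on
raw supporting-read counts by default (`log1p` transform available). Cutoff
calibration reports the full sensitivity/specificity table over candidate
cutoffs and selects by Youden's J (ties to the smaller cutoff); sensitivity
is direction-matched (a truly up-regulated locus only counts when called
up). Truth labels for calibration come from Mann–Whitney tests (exact
enumeration when both groups ≤ 8 and tie-free, tie-corrected normal
approximation otherwise; fully degenerate data gives p = 1) with Holm
step-down correction across loci.

The qAMP index averages three per-enzyme estimates on a 0–100 scale:
`100·2^−ΔCt` for the methylation-sensitive HhaI and HpaII (the surviving,
amplifiable fraction after digestion is the methylated fraction) and
`100·(1 − 2^−ΔCt)` for the methylation-dependent McrBC. Negative ΔCt values
are clamped to 0 (well-to-well noise, not biology) and the index to
[0, 100]. Missing enzymes reduce the average and flag the result. Primer
efficiencies below 1.85 trigger a warning, not a failure.

## What the synthetic study emulates — and what it does not

The generator plants, per seed: a random-background genome; L1 copies of
L1PA1–L1PA8 derived from per-subfamily consensus stubs with a per-copy
divergence ladder (4% for L1PA1 up to 11% for L1PA8) and variable 5′/3′
truncation; host genes, about half containing an intronic L1 (spliced out of
the mature transcript); antisense LCTs at the +450/+200 hotspots (60/40 mix)
with ~2.9% spliced 5′ ends and half non-polyadenylated; stranded 280–340 bp
paired-end libraries for 3 control and 8 tumor samples with per-locus
standardized effect sizes (half up at |δ| = 2, 10% down); long reads with
exponential 5′ loss (mean 30 bp), ~10% undetected loci and ~15% MapQ
failures; qPCR Ct tables (baseline 22 cycles, efficiencies 1.86–2.0, noise
SD 0.15 cycles, planted effects re-used as log2 fold changes); qAMP
quadruples encoding per-locus methylation fractions (0.5–0.95, a third of
tumors hypomethylated by 0.28); CNV log2 ratios (gain +0.58 / loss −1.0);
and an H3K36me3-like coverage track elevated over expressed loci. Sample
sizes, insert range, hotspot positions, splice fraction, polyA fraction and
the methylation/CNV magnitudes follow the study design this package
addresses; where no value is dictated, defaults were chosen once at
realistic scales and are documented here.

Deliberate simplifications, hence what passing tests do **not** show about
real data:

* **Mappability.** The divergence floor (4% per copy) makes two copies of
  the same subfamily almost surely distinguishable over a 100 bp read
  window, so planted truth is recoverable and the recovery tests are
  well-posed. Real L1HS copies are far less diverged; on real data a
  fraction of reads is genuinely unassignable and recall at young loci will
  be lower than the simulator suggests. The ambiguity guard handles the
  residual simulated ambiguity and is the hook where real-data users feel
  this limitation.
* No indels, PCR duplicates, quality-score structure, coverage biases or
  chimeric artefacts in short reads; long reads have 5′ loss only, no
  internal errors and a single alignment block.
* Mature host-gene mRNAs splice out embedded L1s entirely; pre-mRNA/intron
  signal (a real source of antisense-looking pairs) is absent.
* The qAMP simulation caps ΔCt at 20 cycles (detection limit), so index
  inversion at the m = 0 and m = 1 endpoints is exact only to ~10⁻⁴.
* One chromosome; no trans-chromosomal artefacts.

## Numerical and design choices

* Coordinates are 0-based half-open internally; rmsk/BED enter as 0-based,
  GTF is written 1-based closed. On the minus strand the UCSC rmsk dialect
  swaps `repStart`/`repLeft`; normalisation happens once at parse time,
  which is the only reading under which the compound 5′-offset/consensus-end
  filter is coherent on both strands.
* Elements shorter than 500 bp at the 5′ end are kept in the reference and
  flagged truncated; the ASP filter already guarantees ≥ 200 bp of 5′ UTR.
* The insert bound is inclusive at exactly 50 000 bp; the match-length,
  unique-length and MapQ bounds are inclusive at 50/30/30; TSS windows are
  inclusive at 500/900.
* The k-mer seed for matching is `min_l1 // (max_mm + 1)` (complete by
  pigeonhole for gapless matches); below seed length 6 the matcher falls
  back to exhaustive diagonal scanning.
* Clustering merges unique intervals whose gap to the growing cluster span
  is ≤ `merge_gap`; this equals the union-find closure of the pairwise
  "within `merge_gap`" relation (verified against a union-find oracle).
  Pooling re-runs the same merge over per-sample loci, making it
  associative and commutative.
* Spearman correlations are tie-corrected with a t-approximation p-value;
  constant vectors are flagged NaN rather than guessed. Locus-level
  correlation families (methylation–expression, CNV–expression) use
  Bonferroni across loci, expression-group testing uses Holm.
* Host-gene fpkm comparisons run Welch's t-test on log2(fpkm+1) by default
  (variance stabilisation); the transform is configurable and medians are
  always reported on the raw scale.
* Every stochastic stage derives its generator from `(seed, stage-index)`,
  so a fixed seed reproduces each output byte-for-byte regardless of which
  stages run.

## Known limitations

Beyond the simulator simplifications above: the finder consumes a
normalised mate-alignment table (or the simulator's truth placements) and
does not itself align reads to the genome; sense-promoter transcripts and
somatic insertions are out of scope; expression is quantified only as raw
supporting-read counts (no depth normalisation), which is adequate for the
rank- and effect-size-based statistics used here but not for absolute
comparisons across libraries of very different depth. The scale used in the
bundled tests (a few hundred elements on a few-megabase toy genome, ~10⁴
read pairs) keeps the full suite under a minute; the algorithms are linear
in reads and elements and have been run at ~300 elements / ~10⁴ pairs in the
acceptance suite.
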