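# Methods

## Per-position statistics and methylation calling

A modified-base pileup row carries, for one (position, strand,
modification code), the read counts `N_mod`, `N_canonical`, `N_other_mod`,
`N_delete`, `N_fail`, `N_diff` and `N_nocall`, with
`N_valid_cov = N_mod + N_canonical + N_other_mod` the reads confidently
classified by the basecaller. Two per-position statistics are computed:

* Fraction Modified, FM = `N_mod / N_valid_cov`;
* Percent Modified, PM = `N_mod / (N_valid_cov + N_fail + N_diff)`.

FM conditions on the confidence filter and is unstable when few reads pass
it; PM counts the filtered-out (`N_fail`) and mismatching (`N_diff`) reads
in the denominator, so it measures agreement among all reads and is the
statistic used for calling. Deletions and no-calls stay out of the PM
denominator, and `N_other_mod` is not added a second time (it is already
inside `N_valid_cov`). PM ≤ FM always holds (the PM denominator is a
superset), and both lie in [0, 1].

A position is called methylated when PM is **strictly** greater than the
call threshold τ (default 0.5, i.e. more than half of all reads support the
modification; τ = 0.3 is the documented lower setting for partially
modified motifs). Records whose total depth falls below `min_total_reads`
(default 5) are flagged low-coverage and not assigned a status; records
with an undefined statistic (zero denominator) are excluded. The upstream
pileup's confidence filter threshold (0.75) is recorded as provenance
metadata only — it parameterises the tool that produced the pileup, which
the simulator emulates through `p_fail`, and is not used in any computation
here.

Coordinates are 0-based half-open throughout, matching BED.

## Motif model

A motif is an IUPAC pattern plus an explicit list of methylated sites,
each `(offset, modification type, on_reverse)`. `on_reverse=True` places
the modified base on the strand opposite the pattern's orientation — the
geometry of bipartite Type I motifs such as `GAAANNNNNNGGG`, where the
adenine at offset 3 carries 6mA on the forward strand while the guanine at
offset 11 faces a 4mC on the reverse strand. Report strings append `*` to
a base methylated on the complement (`GAAANNNNNNGG*G`); for palindromes
the mirrored partner position is starred as well (`GAT*C`, `CCWG*G`),
since the palindromic site is methylated symmetrically on both strands.

Scanning reports every match of the pattern on the plus strand (strand
`+`) and every plus-strand match of its reverse complement (strand `−`),
both keyed by the leftmost plus coordinate. Palindromic motifs therefore
produce two occurrences per start — deliberately, because the two strands
carry distinct methylatable bases. Overlapping occurrences are all kept.
Genome-side ambiguity letters (e.g. from masking) match only pattern `N`,
a conservative choice so that masked positions cannot satisfy a specific
pattern character.

Summaries are per methylated site: the fraction of occurrences whose base
is called methylated at τ (occurrences without a pileup call count as
unmethylated and are also reported as no-data, with the with-data fraction
given alongside, since the convention for missing occurrences varies
between tools), and the mean PM over occurrences with data.
`fraction_explained` is the share of all methylated calls of one
modification type that coincide with some motif's methylatable position —
the quantity behind "how much of the methylome do the motifs explain".

### De novo discovery

The finder is a deliberately simple greedy procedure, adequate for planted
or strongly enriched motifs: extract the ±`context_k` (default 10)
reference context of every methylated base, reverse-complemented for
minus-strand calls so the modified base is centred in canonical
orientation; for each window width 4..`context_k` and each anchor offset,
count exact words; keep words with support ≥ `min_sites` (50) and
fold-enrichment ≥ `min_fold` (4) over the genome-composition expectation
conditioned on the fixed centre base; merge words differing in exactly one
column into IUPAC degenerate codes; trim uninformative edge `N` columns;
and select maximal non-redundant candidates by support, specificity and
length, skipping candidates that add fewer than `min_sites` new sites.
Merging only ever unions observed variants, so a degenerate position stays
as narrow as its support — `CAGDAC` is reported as `D`, not widened to
`N`, when the C variant has no methylated occurrences. The defaults are
set so that planted-motif recovery is sharp; motifs below `min_sites`
occurrences are (correctly) not reported, mirroring the known failure mode
of motif detectors on rare motifs.

## Genomic context

Per-gene density is the number of methylated bases (PM > τ, both strands,
one count per (position, strand)) divided by the annotated gene length
`end − start`; nothing restricts counting to the coding strand. The top
fraction (default 5%) of genes by density is flagged globally, flagging
exactly `ceil(0.05 N)` genes with ties at the cutoff broken by gene id so
the flagged set is deterministic.

Window density is the mean of **raw** PM values (no threshold) over
1000-base tiling windows, averaging only positions that have a value;
windows without values are emitted as undefined rather than zero, because
a value-wise mean is what "averaging raw PM values" denotes. The final
partial window is included.

PM histograms per feature class use bins covering [0.1, 1.0] (default nine
0.1-wide bins); values below 0.1 — the overwhelming unmethylated
background — are excluded so the distribution of the informative range is
visible.

Regulatory regions: for a plus-strand gene `[s, e)` the promoter is
`[s−40, s)`, the gene start `[s, s+40)` and the gene end `[e−40, e)`,
mirrored for minus-strand genes, clipped to the contig; start/end regions
never extend beyond the gene (they may overlap inside genes shorter than
80 bases). 40 bases captures the bacterial core promoter including the
−10 and −35 elements. Strandless features (ori) carry no regions. The
genome region fraction is the length of the **union** of all three
interval sets over the genome length — overlapping regions of adjacent
genes count once. At a typical bacterial gene density (~1 gene per 1.1 kb,
mean length 1 kb) this fraction computes to ≈ 0.109. Motif region
proportions judge membership by the methylated base's position, not the
motif span, and a base inside several categories counts once per category
(the categories are reported separately).

## Strand-specific ambiguity detection

The basecalling-error pattern modelled: on the strand carrying a 6mA, the
G immediately 5′ of the methylated adenine is miscalled A in a fraction of
reads. In plus-strand base space this produces an A/G mixture (IUPAC `R`)
when the modification is on the plus strand, and a C/T mixture (`Y`) at
the position opposite a minus-strand G when it is on the minus strand —
the two cases are the same phenomenon in mirror image.

The strand-split count table stores, per (position, strand), basecall
counts with minus-strand reads complemented onto the reference strand.
A position is ambiguous when, on at least one strand with depth ≥
`min_cov` (default 10), the two most frequent bases form an A/G or C/T
pair and the minor base's fraction is ≥ `min_minor_frac` (default 0.2).
These defaults are chosen so that binomial sequencing noise at 100×
(per-base error ~1%) essentially never triggers: the probability of ≥ 2
of 10 (let alone ≥ 20 of 100) errors at one position is negligible. Other
mixtures (e.g. A/C) are not methylation signatures and are ignored rather
than masked.

Association is strict immediate adjacency: an `R` at plus position p links
to a methylated 6mA call at (p+1, +); a `Y` at q links to a 6mA at (q−1,
−) — on the minus strand, read 5′→3′, that adenine is the G's immediate
neighbour. No windowed search is attempted.

`count_discordant` is the annotation-free analogue (usable straight from
strand-split counts without any methylation calling): a position counts as
discordant when at least `min_frac` of one strand's reads disagree with
the opposite strand's majority base (complement-consistent, both strands
at depth ≥ `min_cov`). A majority-vs-majority rule would be blind at
miscall rates near 0.5, where the majority is a coin flip; the
fraction-based rule detects every planted site at rate 0.5 and none on
clean data.

Masking replaces each ambiguous base by its code (`R`/`Y`), validating
compatibility with the reference base. The context PFM stacks the
reference windows `[p−k, p+k]` around the sites, reverse-complemented when
the discordant strand is minus so every context reads 5′→3′ on the
erroneous strand; rows are normalised to sum to 1.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:

* **Genome**: i.i.d. bases at a configurable GC content (default 0.5);
  one contig by default. No repeat structure, no skew, no real
  genome-scale composition — the analyses do not depend on genome realism.
* **Planting**: motif occurrences are placed non-overlapping at
  uniform-random eligible positions on a random strand, degenerate
  positions instantiated uniformly. Methylation then acts genome-wide:
  **every** occurrence of a configured motif — planted or accidental — is
  methylated per site with probability `p_site`, as a methyltransferase
  recognising its motif everywhere would do; the manifest of planted
  occurrences records only deliberate plantings. `p_site` is drawn
  independently per (occurrence, meth site), so each summary row's
  expected methylated fraction equals `p_site`.
* **Pileup**: constant depth per position (default 100 reads per strand,
  the emulated study's coverage target). Per record, `n_fail ~
  Binom(cov, p_fail)` then `n_diff ~ Binom(cov − n_fail, p_diff)`
  (sequential thinning keeps the remainder non-negative); at methylated
  sites `n_mod ~ Binom(n_valid, p_read)`, elsewhere 0. Off-motif
  positions become spuriously methylated with per-base probability
  `background_call_rate` and then receive the same per-read signal.
  `n_delete` and `n_nocall` are emitted as 0 — no formula uses them.
  Coverage-dependence effects are emulated by lowering the constant depth
  (an optional Poisson-depth variant was considered and dropped: it adds
  nothing the analyses are sensitive to).
* **`p_read` default 0.9**: per-read modification-call probabilities at
  truly methylated sites are not observable from pileups; 0.9 puts the
  simulated mean PM at ≈ 0.83, inside the 70–90% band typical of
  consistently methylated 6mA motifs, and `p_read ≈ 0.6` reproduces the
  partially-modified regime (mean PM ≈ 0.55, ~10% of occurrences below
  the 0.5 threshold but > 95% above 0.3).
* **Strand counts**: error-free except at planted G-before-6mA contexts,
  where the methylated strand's G reads are miscalled A with probability
  `ambiguity_error_rate`, plus an optional uniform error floor (default
  0).

Reproducibility is a contract: identical config + seed produce
byte-identical FASTA/GFF3/bedMethyl/TSV outputs (each stage uses an
independent child stream of the seed).

Because background sequence and placement are i.i.d., passing tests show
that the implementations compute their definitions correctly and recover
planted parameters under the modelled noise — they do not show robustness
to real-data features such as coverage dips, repeat-induced mapping
artifacts, contaminating modifications, or motif-context-dependent error
rates beyond the single modelled G→A pattern.

## Numerical and design choices

* Thresholds are strict (`>`), including the PM = 0.5 boundary, matching
  the definition of "above".
* Low-coverage records (< 5 total reads) are flagged, not called; the
  floor is a package choice, as PM's motivation is precisely false
  positives at low valid coverage.
* Palindrome occurrence convention: one occurrence per strand per start;
  summaries are per methylated site, so a palindrome reports one row whose
  occurrence count pools both strands.
* `flag_top` tie-break: lexicographic gene id, purely for determinism.
* Whether the `N_diff` count excludes deletions is ambiguous in the
  upstream tooling; deletions are kept out of the PM denominator here.
* COG grouping keeps the first letter when a gene carries several.
* Empty inputs yield empty-but-typed outputs (empty matrices are flagged
  via `n_sites = 0`; undefined fractions are `None`), never NaN
  arithmetic.
* Pipeline outputs are written with fixed float formatting and stable
  ordering so that identical inputs give byte-identical reports.

## Problem sizes

Tests and the acceptance script use simulated genomes of 10–200 kb with
100–500 planted occurrences at 100× depth — sizes at which binomial
parameter-recovery intervals are tight (a 200 kb genome yields ~2500 GATC
occurrences, giving a ±1% band around `p_site` at 99% confidence) while a
full run of suite plus script stays under a minute of compute.

## Known limitations

* The de novo finder handles exact-word enrichment with single-column
  degeneracy merging; it will not assemble bipartite motifs with long
  spacers from scratch (evaluation of a given bipartite motif works
  fully). Joint both-strand discovery is out of scope.
* Replicate comparison assumes call sets on the same reference
  coordinates; no lift-over is attempted.
* The ambiguity module consumes strand-split count tables, not BAM; a
  BAM-to-counts adapter is a possible convenience layer, deliberately not
  part of the core path.
* No statistical significance testing of regional enrichment is provided —
  proportions are reported against the genome-fraction null only.
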