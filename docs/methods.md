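# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `tepav`, and what the synthetic tests do
and do not demonstrate about real data.

## Genotyping model

A TE insertion that is present in a resequenced line attracts reads
across its internal sequence, including the 10 bp windows just inside
its start and end; an absent insertion attracts almost none there, apart
from mismapping from related copies elsewhere in the genome. The
classifier therefore uses three predictors per (TE, sample): the
MQ ≥ 20 read count over each edge window and the TE order. Window
support is the number of overlapping primary alignments (the semantics
of `bedtools multicov`, which counts reads touching an interval by at
least one base); a per-base mean-depth variant is available behind
`mode="mean_depth"` because "mean coverage" is ambiguous between the two
readings, but counts are the default and the canonical feature.
Secondary, supplementary and duplicate alignment records are always
excluded — only the MQ filter is part of the published protocol, the
rest is fixed here for determinism. TEs shorter than 20 bp get
overlapping windows; shorter than 10 bp, both windows are the whole
element.

The forest is a `RandomForestClassifier` with 500 trees, no depth limit
and all three predictors considered at every split (with three
predictors a random subspace would add little); the order is one-hot
encoded. Training draws a balanced sample (~50% present) of labeled
(TE, sample) records without replacement, capped by class availability
with a warning. Cross-validation is stratified 10-fold repeated three
times; the reported accuracy is the mean over the 30 fold evaluations
and the SE is computed across the three repeat means, a convention fixed
here because "mean (SE)" does not itself define the SE's unit. The
sampling unit is the labeled (TE, sample) count record, since a single
TE yields one record per resequenced sample per assembly.

Two models are trained from identically structured inputs at 15× and
30× nominal depth; at inference a sample's realized coverage — the sum
of MQ-filtered aligned bases divided by assembly length, as opposed to
theoretical depth from raw read counts — selects the model, ≥ 25×
going to the 30× model. The probability-of-presence thresholds are
inclusive: ≥ 0.7 present, ≤ 0.3 absent, strictly between ambiguous, so
every probability receives exactly one label.

Post-classification, a TE is dropped if its own assembly's reads do not
yield a present call (recalcitrant to short-read genotyping), and if
more than 25% of its non-missing calls are ambiguous — strictly more
than, so exactly 25% is retained. The denominator excludes missing
cells, a choice made here because the 25% rule does not define its
denominator.

## Population frequencies

Frequency is presents / (presents + absents). Ambiguous calls are
no-calls and are excluded from the denominator (the alternative —
counting them in — would bias every frequency toward whichever class
the ambiguous cells secretly belong to). Homologous TEs annotated in
several assemblies are collapsed by the arithmetic mean of their
per-assembly frequencies over the members that survived filtering;
metadata comes from the group's designated source assembly, falling back
to the first retained member when the source member was filtered.

Bin boundaries follow the wording "low (<20%), moderate (20–80%), high
(>80%)" literally: both 0.20 and 0.80 are moderate. Likewise LTR
similarity 95 and 99 are both moderate. LD classes put r² = 0.9 and 0.5
in the moderate bin, with high strictly > 0.9.

The Kolmogorov–Smirnov test uses the asymptotic two-sided p-value; only
the D statistic is load-bearing in the analyses, and tests verify it
against a brute-force ECDF scan. The two-sided Fisher exact p is the
minimum-likelihood convention (sum of hypergeometric probabilities of
tables no more probable than observed, with a 1e-7 relative tie
tolerance), verified against exact-fraction enumeration for all tables
with N ≤ 30. Degenerate margins raise rather than returning p = 1.

## Nested elements

Nesting is taken from an annotation attribute when one exists, otherwise
recomputed as strict interval containment (the smallest containing
element is the immediate parent; identical intervals are not nesting).
Multi-level nests contribute one pair per parent–child edge only. Since
a nested copy cannot exist in a genotype without its host, the outer
frequency must be at or above the nested frequency in truth; the
consistency summary bins outer − nested deltas at 0 and at −0.05, the
5% tolerance being an absolute frequency difference. In the similarity
ordering, ties count as "not higher" — the conservative reading. Pair
frequencies use nonredundant merged values when available, else
single-assembly values.

## Gene context

The 13 proximity categories are assigned hierarchically; the first
applicable category wins, checked per gene: gene completely within the
TE; TE completely within the 5′ UTR, 3′ UTR, an exon, an intron, the
gene body; 0–1 / 1–5 / 5–10 kb upstream; 0–1 / 1–5 / 5–10 kb
downstream; intergenic (> 10 kb from every gene). "Completely within"
is closed-interval subset; a TE partially overlapping a gene falls
through to the flank rules with distance zero, assigned to the 0–1 kb
bin on the side where it sits relative to the gene midpoint. Flank
distances run from the gene's strand-aware boundary to the nearest TE
edge, with half-open bins (0, 1000], (1000, 5000], (5000, 10000]. When
a gene has several transcripts, the transcript with the longest spliced
length defines exons and UTRs.

Bootstrap backgrounds are order-matched: a category with k members of a
given order is compared against n_boot = 100 resamples of k TEs drawn
with replacement from all TEs of that order. Child RNG streams are
keyed per (order, category) so enlarging n_boot extends rather than
reshuffles the iteration sequence; note that the resulting
"max shift ≤ 2 SE" stability diagnostic is itself a random variable
whose per-cell exceedance probability is a fraction of a percent, so at
some seeds a single cell can land just above 2 SE.

Region membership (e.g. low-recombination intervals from BED) uses the
TE midpoint against merged regions, closed at both ends.

## Linkage disequilibrium

Inbred lines are coded haploid 0/1; heterozygous SNP calls are set
missing with a count report, and ambiguous TE calls map to missing. On
the pairwise-complete subset, D = p_AB − p_A p_B,
r² = D² / (p_A(1−p_A) p_B(1−p_B)), and D′ = |D| / D_max with D_max the
usual sign-dependent bound; a marker monomorphic on the complete subset
makes the pair undefined, flagged and excluded from summaries. SNPs
positioned inside any TE interval (closed) are removed before analysis.
The tag-SNP search window is ±1 Mb around the TE midpoint; ties on the
metric break by smallest physical distance, then lowest coordinate for
determinism. No minor-allele-frequency filter is applied to TE markers.

## The synthetic generator

Defaults describe the study conditions the pipeline is tested under:
200 samples × 2,000 TEs at 30× depth, order mix 70% LTR / 20% TIR /
10% Helitron, per-TE frequencies from a U-shaped Beta(0.5, 0.5), 10%
nested elements, and per-window counts Poisson(depth · λ) with
λ_present = 1.0 and λ_absent = 0.02 (mismapping floor), plus 2% of
entries drawn at half depth to create genuinely uncertain cases; an
overdispersion knob switches to negative-binomial noise for stress
tests. Poisson is the default for analytic transparency. Per-sample
depth jitters ±10% around nominal, exercising the model-selection
switch.

The age model maps frequency monotonically to expected LTR similarity
(100 − 15·f, Gaussian noise SD 1.5, clipped to [0, 100]): older
insertions have had more time both to rise in frequency and to diverge
their LTRs. With zero noise the map is strictly monotone, pinning the
similarity–frequency Spearman correlation at −1. Nested TEs take
frequency f_host · U(0.3, 1) and their presence is conditioned on host
presence per sample — no independent excision — so the containment
ordering holds exactly in truth. Because the ratio can approach 1, a
minority of pairs have near-zero truth deltas and can flip sign under
classifier noise; at the default conditions about 4–6% of pairs do,
which is what the post-noise consistency checks reflect.

Tag SNPs are designed by copying a TE's presence vector and flipping
each allele with the probability q solving
(1−2q)² p(1−p) / (p_y(1−p_y)) = r²_target, found by root-finding on
[0, 0.5] (the closed form depends on allele frequency); target 0 draws
an independent SNP at the same frequency. Realized r² is recorded per
design.

What the generator does **not** emulate: population structure and
kinship, linkage between TE loci, reference bias, length- or
family-dependent mappability, and read-level artifacts. Passing the
recovery tests therefore shows the pipeline is correct and
well-calibrated under its own statistical assumptions, not that real
maize data would yield the same accuracy.

## Problem sizes and tolerances

The acceptance checks run at desk scale: the classifier-recovery panel
is the generator default (200 × 2,000 at 30×) with a balanced training
sample of 20,000 records rather than the 500,000 used at population
scale; the designed-LD panel uses 500 samples × 300 TEs with 200
replicates per target; oracle equivalences use 1e-12 (LD), 1e-10
(Fisher) and 1e-12 (KS) tolerances; all randomness is seeded and the
whole train → classify path is bit-reproducible under a fixed seed.
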