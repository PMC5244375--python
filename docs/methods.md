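# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic cohorts do and do not emulate, and
the known limitations.

## Coordinate and naming conventions

All genomic intervals are 0-based half-open internally; BED outputs stay
0-based and human-readable tables are 1-based inclusive. Chromosome names
are normalised on ingest (case-insensitive, optional `chr` prefix
stripped). A probe is anchored at its midpoint — the arrays use 50-mer
probes and no convention fixes which base represents them, so the midpoint
is used throughout. X and Y are excluded from every analysis stage;
autosome filtering logs the number of items removed.

Promoter windows span 5 kb upstream and 1 kb downstream of the TSS,
oriented by strand. For multi-TSS genes the 5′-most TSS *in transcription
orientation* is used (smallest coordinate on +, largest on −): "upstream"
is strand-relative in a promoter context. A probe overlapping several gene
bodies or windows counts for each gene; since results are reported
per gene, multi-assignment is the neutral choice and no tie rule is
needed. Copy-number probe→gene assignment defaults to gene bodies
(`mode="promoter"` is available); nothing in the calling logic depends on
the choice, only which probes aggregate to which gene.

## Differential expression

Two-group (tumour vs normal, unpaired) empirical-Bayes moderated t. Per
gene, the pooled residual variance s²_g has d = n₁+n₂−2 degrees of
freedom. Hyperparameters are estimated by method of moments on the log
variances: with e_g = log s²_g − ψ(d/2) + log(d/2),

* trigamma(d₀/2) = Var(e) − trigamma(d/2), solved by Newton inversion;
* s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).

When Var(e) does not exceed the pure chi-square expectation the prior
degrees of freedom are infinite (complete pooling, with a logged warning);
when every gene has *exactly* the same variance the prior is set to that
common value, so shrinkage is an exact fixed point and the moderated t
coincides with the ordinary pooled t. `prior_df=0` disables moderation.
Zero-variance genes are handled by the shrunken variance (always positive
when s₀² > 0). p-values come from t(d₀+d), a normal when d₀ is infinite.

Significance is gated on BH-adjusted q-values by default (configurable to
raw p): q < 0.05 and |log2FC| ≥ log2(2). Fold change is the difference of
group means on the log2 scale. The pairing of most tumour/normal samples
in such designs is ignored (unpaired model), matching the two-group
description of the study design; a paired model would need a matched
sample map the inputs do not carry.

A development-time cross-check against the reference empirical-Bayes
implementation in R (limma's `eBayes`) on a 2,000-gene null matrix agreed
to ~1e-15 on both t and p. The shipped test suite instead uses
self-contained oracles: a hand-computed unmoderated example, recovery of
planted (d₀, s₀²) from simulated scaled-inverse-chi-square variances, null
type-I calibration, and a definition-based BH oracle.

## Copy number

**Normalization.** GC bias is removed by subtracting a lowess fit of the
log2 ratio against probe GC fraction (span 0.3); if array grid coordinates
are present, a 9×9 moving-median surface over the grid is also subtracted;
the result is re-centred to zero median. Both corrections are off in the
pipeline by default because the simulator's bias amplitudes default to 0;
they are exercised directly by tests with constructed biases.

**Segmentation.** Circular binary segmentation: for the probe sequence of
one chromosome, the arc [i, j) maximizing

    |mean(arc) − mean(complement)| / sqrt(1/k + 1/(n−k))

is found exhaustively (the centred-cumulative-sum identity
stat = |g(j)−g(i)|·sqrt(n/(k(n−k))) makes this one O(n) pass per width;
an arc and its complement give identical statistics, so contiguous arcs
cover the circular family). Split significance uses raw permutations of
the probe values (default α = 0.01, 1,000 permutations; fewer than 100
draws a warning). The permutation loop stops early as soon as the
exceedance count proves p > α — a pure speed optimisation that cannot
change any accept/reject decision. Accepted splits recurse into the
resulting pieces; segment means are recomputed from member probes. There
is no post-hoc pruning or hybrid p-value approximation; minimum arc width
defaults to 2 probes. Degenerate all-equal input yields one segment
without testing.

**Calling.** Sample noise is the *unscaled* MAD (no 1.4826 factor) of
observed-minus-segmented residuals — the 2× threshold is calibrated
against the MAD as such. The per-sample centre is the unweighted median
of autosomal segment means ("median segment", not probe-weighted). A
segment is gain/loss when its mean is more than k·max(MAD, mad_floor)
from the centre, k = 2; `mad_floor` (default 0.01) guards the noiseless
degenerate case where MAD = 0 would flag every non-central segment.
Probes inherit their segment's status.

**Recurrence.** Per-probe gain/loss fractions across tumours with a 1/3
cutoff (so ⌈n/3⌉ tumours when fractional, 4 of 12 exactly). Gene status
per sample is the plurality of its mapped probes' statuses (a call must
beat both rival counts; gain/loss ties are neutral) after intergenic
probes are excluded; gene-level fractions are reported in the
"41.7%, 5/12" style. Recurrence is declared probes-first by default
(probe statuses → gene status per sample → fraction across samples).

## Methylation

**Scoring.** For each probe, the values of all probes within ±375 bp on
the same chromosome form the window; the background is every other
autosomal probe on the array (a seeded subsample of 50,000 when the array
is larger). The one-sided statistic is D⁺ = sup_x [F_bg(x) − F_win(x)]
(right-continuous ECDFs; ties allowed), testing whether the window is
stochastically *larger* (hyper); hypo is the same test on negated values,
which makes direction antisymmetry exact by construction. The p-value is
exact when m·n ≤ 10,000 — a lattice-path dynamic programme over all
interleavings, validated against full enumeration and against
`scipy.stats.ks_2samp(method="exact")` — and otherwise the one-sided
asymptotic tail exp(−2mnD⁺²/(m+n)). Scores are −log10 p with p floored at
1e−300.

**Peaks and annotation.** Peaks are maximal runs of ≥ 2 consecutive
probes (per direction, never spanning chromosomes) with score ≥ 2.
The score threshold of 2 corresponds to p ≤ 0.01; the frequently quoted
equivalence "score 2 ⇔ p < 0.05" does not hold (−log10 0.05 ≈ 1.3), so
both the threshold and its interpretation are configuration keys and the
numeric default is 2. A peak annotates every gene whose promoter window
it overlaps by ≥ 1 bp; the gene's promoter score averages the mean scores
of its overlapping peaks, and the aberrant fraction divides the window's
probes inside called peaks by all interrogated probes in the window
(records for windows with zero interrogated probes are suppressed with a
warning). Hyper and hypo are tabulated separately end to end.

**Recurrence.** A gene qualifies in a sample when it has ≥ 1 annotated
peak (optionally also `min_fraction` on the aberrant fraction); genes are
"frequent" when strictly more than 60% of tumours qualify.

**A calibration note.** With single-probe windows (8 kb spacing vs 750 bp
windows) the one-sided p is bounded below by ~e⁻² ≈ 0.135, so a score of
2 is unreachable and no peaks can ever be called; peaks require locally
dense tiling, which the promoter tiles provide. Dense tiling also means
neighbouring windows share probe values, so their scores are correlated
and false 2-probe peaks arise at roughly 0.3–0.5% per promoter, direction
and sample under pure noise — a direct consequence of the p ≤ 0.01
per-probe threshold, not an implementation artifact. Such false peaks
cover only a sliver of a promoter (aberrant fraction ≈ 1/3), whereas
planted events cover essentially all of it (≈ 1), so the exposed
`min_fraction` gate (e.g. 0.5) removes them; the default qualifying rule
remains any-peak.

## Synthetic cohorts

The generator emulates the three array layers for T tumours and N normals
(defaults 12 and 9): aCGH probes at 4 kb spacing with GC fractions and
array grid coordinates, methylation probes at an 8 kb backbone plus a
5-probe tile at 250 bp spacing across each promoter, and evenly spaced
alternating-strand gene models. Signals are additive: planted segmental
shifts (sign from gain/loss), planted promoter shifts (sign from
hyper/hypo) over the gene's promoter probes, quadratic GC bias g(gc)
centred at 0.5 and a one-cycle sinusoidal grid surface h(row, col) (both
amplitudes default 0 so stages can be tested in isolation), and Gaussian
noise (defaults: aCGH 0.15, methylation 0.2, expression 0.5 — chosen so a
single-copy gain at 50% purity, log2 ≈ 0.58, sits at ~4× the aCGH noise,
and promoter shifts of ±2 are unambiguous against capture noise).
Expression couples to the planted layers as
baseline + β_cn·(CN shift) + β_meth·(meth shift) + direct planted effects
+ noise, with β_meth expected negative for hypermethylation. Each event
is assigned to round(recurrence_fraction·T) tumours by a seeded draw; each
(layer, sample) pair has its own pseudo-random stream derived from the
master seed, so growing the cohort never perturbs existing samples.

What the simulator does **not** emulate: raw two-colour intensities,
scanner/spatial artifacts beyond the smooth surface, probe sequence
effects beyond the GC covariate, capture efficiency or CpG density,
genome-build idiosyncrasies, or correlated biological heterogeneity
(tumour purity, subclones). Passing recovery tests therefore demonstrates
the *algorithmic* correctness of each stage under its stated noise model,
not performance on real arrays.

## Problem sizes in tests and the acceptance script

The validation cohorts use 2–4 chromosomes of 0.4–2 Mb with 8–240 genes,
200–1,000 probes per layer and 200–1,000 CBS permutations; the end-to-end
concordant design uses 2 chromosomes × 1.2 Mb, 60 genes and 12 vs 9
samples, replicated five times in the acceptance suite. These sizes keep
every stage's statistics in the same regime as full-scale arrays (noise
levels, window occupancies, recurrence arithmetic are identical) while
each run completes in seconds to a couple of minutes.

## Known limitations

* CBS here is deliberately plain: no hybrid tail approximation, no
  undo-SD pruning, no between-array wave correction; exact parity with
  DNAcopy is not claimed (or needed for the planted-event regimes tested).
* The moderated t assumes independent genes when estimating (d₀, s₀²);
  strong co-expression inflates the apparent spread of variances.
* The KS exact null assumes no ties; with heavily tied data the exact
  p-value is conditional on ranks in the usual approximate sense.
* Integration treats a gene unassessed in a layer as excluded from that
  layer's intersections (not as negative), so concordance counts are
  conservative with respect to missing data.
* Percentage summaries follow reporting conventions (integer for
  probe-level, one-decimal for gene frequency); gain and loss probe
  percentages can sum above 100 because a probe may be gained in one
  tumour and lost in another.
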