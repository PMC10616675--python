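# Methods

## Decay model and percent remaining

Each transcript is assumed to decay by first-order kinetics after
transcription shut-off: a_g(t) = a_g(0)·exp(−k_g t), with half-life
t½ = ln 2 / k_g. Observed counts are converted to normalized counts per
kilobase (count / size factor / (length_bp/1000)) and then to percent
remaining, P_g(t) = 100·x_g(t)/x_g(0), **anchored per subject**: each
mouse's own t = 0 library is the denominator. This matches a design with
one library per mouse per timepoint, makes every curve start at exactly
100, and cancels subject-level scale effects (percent remaining is
invariant to multiplying all of a subject's libraries by a constant). A
genotype-mean-anchored mode is not provided because the paired layout is
the package's unit of replication; subjects whose anchor value is zero
yield missing values for that gene.

The normalization method for decay curves is median-of-ratios by default
(factors from the geometric-mean reference profile over genes nonzero in
all samples, rescaled to geometric mean 1), with `total_count` and `none`
selectable. `none` exists because the closed-form identity
P = 100·exp(−kt) only holds without between-library rescaling; any
data-driven normalization of a chase experiment re-anchors each library to
the shrinking RNA pool and inflates slow decayers — the well-known
actinomycin-D normalization artifact. The artifact is a property of the
measurement, not a bug: it is reproduced by the simulator, demonstrated by
tests, and deliberately not corrected (no spike-ins are modeled).

## Filter cascade

Genes enter the screen only if: mRNA biotype; not in the exclusion list
(knocked-out family genes and the artefactually elevated Plekhg2, matched
on identifier or symbol); mean control FPKM at t = 0 at least 0.1
(FPKM = count·10⁹/(library size·length)); control mean curve strictly
below 85% remaining at 120 min (or the latest grid time at or before it,
recorded in the report); and a defined anchor. Reasons are computed
independently on the full input, so a gene may carry several and the
cascade is order-free.

## Two-stage stabilization screen

**Stage 1.** At every post-anchor timepoint, an unpaired two-tailed
two-sample t test compares per-subject percents between genotypes
(equal-variance by default; Welch by flag). A gene passes when some run of
3 consecutive post-anchor timepoints all have p < 0.008 with the knockout
mean above the control mean. The 0.008 cutoff is treated as a fixed
Bonferroni-style constant (≈0.05 spread over the post-anchor tests) rather
than a data-dependent correction; raw p-values are always reported so any
cutoff can be re-applied. The source methods give 0.008 in the text and
0.0008 in the supplementary legends; 0.008 is the default and the value is
a config knob (`stage1_alpha`). The anchor is excluded from testing (both
groups are identically 100 there); the direction requirement exists
because the screen targets *stabilized* transcripts, not merely different
ones.

**Stage 2.** Stage-1 passers get a mixed-design (split-plot) two-way
ANOVA: between-subject factor genotype, within-subject factor time (anchor
included as a level), subject nested in genotype. The classical sum-of-
squares decomposition is used (weighted sums for mildly unbalanced groups
after dropping subjects with incomplete curves). Sphericity of the time
levels is corrected with the Greenhouse–Geisser ε computed from the pooled
within-group covariance of the time levels (the SPSS/Prism convention;
pooling across groups after removing group means), via the double-centered
trace formula ε = tr(S*)²/((k−1)ΣS*²), clamped to [1/(k−1), 1]. Within-
subject F tests keep their value and scale both degrees of freedom by ε.
Per-timepoint genotype comparisons are Šídák-adjusted over the m
post-anchor timepoints: p_adj = 1 − (1 − p)^m. The gate term is the
genotype×time interaction by default — with both genotypes pinned to 100%
at the anchor, stabilization *is* an interaction — with the genotype main
effect selectable; both are always reported.

Useful reductions, all verified in tests: with a single time level the
genotype F equals the squared equal-variance t statistic; with two time
levels ε = 1 exactly and corrected p equals uncorrected p; F and
uncorrected p for all three terms agree with pingouin's independent
implementation to 10 significant digits (pingouin's ε estimate differs by
convention: it pools the grand covariance across groups, which absorbs
between-group mean differences).

**Ranking and half-lives.** Stabilized = stage-1 ∧ stage-2. Genes are
ranked by the mean knockout-minus-control difference in mean percent
remaining at 60 and 120 min, ties broken lexicographically by identifier.
Half-life is the first downward crossing of 50% on the mean curve, linear
interpolation on the percent scale between the bracketing grid points
(log-scale interpolation by flag — exact for a pure exponential; the
linear default reads mean curves the way a bench scientist does); a curve
touching exactly 50 at a grid point returns that point; a curve never
reaching 50 returns a right-censored value at the grid maximum, printed
">120 min" on the default grid. On the default grid the linear
interpolation recovers a noise-free 20-min half-life as 20.9 min (the
interpolation error bound of ±1 min is dominated by curve convexity
between 15 and 30 min).

## Motif scanner

Exact-match search for UAUUUAU, UAUUUUAU, UUAUUUAUU and UUAUUUUAUU over
the sense strand only (3′-UTRs are supplied in mRNA orientation).
Sequences are normalized to uppercase RNA (T→U) before matching; N never
matches; all occurrences are reported including overlapping ones, with
1-based inclusive coordinates; a maximal-site view (hits not contained in
a longer hit) is derived, but `has_site` — the screen's primary output —
is view-independent. Genes with multiple UTR records take the union of
hits. Equivalence with an exhaustive all-substring oracle is asserted on
1,000 random 200-nt sequences.

## Differential-expression thresholds

The DE engine is consumed, not reimplemented. Gates: |log2FC| ≥ 0.3785
(= log2 1.3, two-sided on magnitude with sign assigning up/down),
adjusted p ≤ 0.05, control mean expression > 0.1, exclusion list applied.
Up and down sets are disjoint by construction and shrink monotonically as
the fold gate rises.

## Induction AUC

AUC is the composite trapezoid of the mean curve (one AUC per gene, no
baseline subtraction, matching ratio-of-areas reporting); window endpoints
between samples are interpolated linearly, which makes AUC exactly
additive over adjacent windows and ratio comparisons invariant to common
rescaling. Peak fold change is the curve maximum over the t = 0 value,
earliest peak on ties.

## Synthetic data: what it emulates, and what it does not

The chase simulator draws, per gene: a log-normal baseline abundance
(log-mean 3, log-SD 1, arbitrary units), a log-normal control half-life
(log-mean ln 30, log-SD 0.35 → bulk between 15 and 60 min), gene length
(log-normal around 1.5 kb, floor 200 bp), and a biotype label (5% non-mRNA
by default so the biotype filter has work to do). A fraction of genes
(default 20%) is non-decaying (k = 0) in all genotypes — without a stable
background the fixed-depth artifact would push every curve above the 85%
filter; a fraction (default 2.5%) is stabilized in the knockout, with
control half-life pinned at 20 min and knockout half-life multiplied by 6
(→120 min), the planted effect size the screen is expected to recover.
Expected counts are abundance × length/1000 scaled so each genotype's
anchor library totals 2×10⁶; later libraries shrink as the pool decays.
Counts are negative-binomial with shared dispersion 0.01 (per-gene vectors
accepted), giving ≈10% CV at the mean depth per gene; `dispersion=None`
yields exact expected values (floats) for closed-form tests. With
`renormalize_to_fixed_depth` (default on, matching real pipelines) every
column is rescaled to the fixed depth — this, and only this, creates the
apparent-increase artifact; integer rounding after rescaling keeps column
sums within ±(number of genes) of the depth. One library per subject per
timepoint; plate-level pooling below the mouse is not modeled because the
mouse is the published unit of replication. The default grid
0/15/30/45/60/90/120 min covers the stated 120-min chase; all statistics
are grid-agnostic and the grid is configurable.

The UTR simulator draws i.i.d. background bases (default mildly AU-rich:
A 0.3, C 0.2, G 0.2, U 0.3) over uniform lengths 200–600 nt and overwrites
the background with motif patterns at non-overlapping recorded positions —
every stabilized gene gets 1–3 sites by default, other genes with
probability 0.2, so site-fraction asymmetries between stabilized and
background sets are built in. Background sequence can also contain chance
motifs; recovery is scored on planted sites only.

The induction simulator uses the pulse v(t) = 1 + (fold−1)·((t/tp)·
exp(1−t/tp))^s, which starts at baseline 1, peaks at exactly `fold` at
`tp`, and relaxes toward baseline at a rate set by the shape s;
multiplicative log-normal noise with chosen CV is applied per replicate.
The noiseless truth curve's trapezoid is the reference AUC.

What passing tests on these simulations do **not** show: real chase data
have gene-specific dispersion, correlated technical effects between
libraries of one batch, multi-isoform UTRs, partial transcriptional
run-on after ActD, and annotation errors; none of these are modeled.
Recovery and calibration results are statements about the generative
model's conditions (n = 4, ~10% CV, 6-fold stabilization), not guarantees
on any real dataset.

## Numerical choices and scale of the built-in checks

t tests and F tails come from scipy; ties and degenerate inputs are
handled explicitly (constant groups give undefined t → p treated as
missing; groups with fewer than two subjects are skipped with a recorded
reason, never silently dropped). Calibration and recovery checks run at
2,000 genes (50 planted stabilized among 1,950 nulls), the scanner oracle
at 1,000×200 nt, ε properties at 100 random shapes — sizes chosen to make
the binomial noise on the measured rates small relative to the asserted
bounds while the whole suite runs in seconds. The null false-positive rate
of the full screen is far below the 1% bound asserted: three consecutive
directional p < 0.008 events plus an ANOVA gate compound to ≲10⁻⁴ per
gene under the null, so the expected number of false calls in 2,000 genes
is well under one.

## Known limitations

Two genotypes per screen call (run pairwise for three-genotype designs);
no spike-in normalization or artifact correction; half-life is read from
the mean curve, not fitted per subject with uncertainty; the ANOVA's
classical sums of squares are exact for balanced designs and an
approximation under unbalance after subject dropping; the DE module trusts
the upstream engine's p-values entirely.
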