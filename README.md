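# decaychase

Transcriptome-wide mRNA decay analysis for actinomycin-D chase RNA-seq
experiments, built around the screen used to find transcripts stabilized in
TTP-family (ZFP36/ZFP36L1/ZFP36L2) knockout macrophages.

## The problem

TTP-family RNA-binding proteins bind AU-rich elements (AREs) in 3′-UTRs and
promote mRNA decay. To find their targets genome-wide, cells are stimulated
(LPS, 1 h), transcription is shut off with actinomycin D (ActD), and RNA-seq
libraries are taken from each mouse at a series of chase timepoints. A
transcript following first-order decay obeys

    a_g(t) = a_g(0) · exp(−k_g t),        t½ = ln 2 / k_g

and its **percent remaining** is P_g(t) = 100 · x_g(t)/x_g(0), anchored at
each mouse's own t = 0 (ActD addition) sample. A transcript is a candidate
direct target when it decays in control cells but is *stabilized* (decays
slower) in the knockout.

Two complications shape the analysis:

1. **Normalization artifact.** ActD shrinks the total RNA pool over the
   chase, but standard library normalization assumes comparable pools, so
   slowly decaying transcripts artefactually appear to *increase* above
   100% remaining. The package's simulator reproduces this regime so the
   screen's behavior under it can be tested; it is modeled, not corrected.
2. **Many curves, few mice.** With n = 4 mice per genotype and ~7
   timepoints per curve, the screen is two-staged: a cheap per-timepoint
   test pre-selects candidates, and a stringent whole-curve ANOVA confirms
   them.

## The screen

After converting counts to normalized counts per kilobase and percent
remaining, genes pass a filter cascade (mRNA biotype only; knocked-out
genes and the artefactually elevated *Plekhg2* excluded; mean control FPKM
at t0 ≥ 0.1; control curve must drop below 85% remaining by 120 min). Then:

- **Stage 1** — unpaired two-tailed t tests (knockout vs control percent
  remaining) at every post-anchor timepoint; a gene passes when p < 0.008
  at three *consecutive* timepoints with the knockout above the control.
- **Stage 2** — mixed-design two-way repeated-measures ANOVA per gene
  (between-subject genotype, within-subject time, subject nested in
  genotype) with the Greenhouse–Geisser ε correction for sphericity and
  Šídák-adjusted per-timepoint comparisons (p_adj = 1 − (1 − p)^m). Genes
  are gated on the genotype×time interaction at α = 0.05.
- Survivors are **ranked** by the mean knockout-minus-control difference in
  percent remaining at 60 and 120 min, and **half-lives** are read off the
  mean curves by linear interpolation of the first downward crossing of
  50%, right-censored (">120 min") when never reached.

A separate module scans 3′-UTRs for the four TTP site classes — UAUUUAU
(7-mer), UAUUUUAU (8-mer), UUAUUUAUU (9-mer), UUAUUUUAUU (10-mer) —
reporting all (including overlapping) occurrences with 1-based coordinates.
Further modules threshold externally produced differential-expression
tables (|log2FC| ≥ 0.3785 ≡ 1.3-fold, adjusted p ≤ 0.05) and compute
induction-curve AUC ratios and peak fold changes.

Everything is developed and validated against a synthetic-data module that
generates chase experiments with known gene-level half-lives, planted
stabilized genes, negative-binomial replicate noise, the fixed-depth
renormalization artifact, and UTRs with planted ARE motifs.

## Worked example

```python
import decaychase as dc

cfg = dc.DecaySimConfig(n_genes=500, seed=7)
experiment, truth = dc.simulate_chase(cfg)
result = dc.run_screen(experiment, ("control", "ko"))

print(f"retained {len(result.table)} of {cfg.n_genes} genes after filtering")
print(f"stabilized calls: {int(result.table['stabilized'].sum())} "
      f"(planted: {len(truth.stabilized_genes())})")
top = result.stabilized_genes[0]
row = result.table.loc[top]
print(f"top-ranked gene {top}: rank metric {row['rank_metric']:.1f}, "
      f"control t1/2 {row['half_life_control_min']:.1f} min, "
      f"KO t1/2 {'>' if row['half_life_ko_censored'] else ''}{row['half_life_ko_min']:.0f} min, "
      f"interaction p (GG) {row['p_interaction_gg']:.2e}")

utrs = dc.simulate_utrs(truth, seed=8)
ann = dc.annotate_gene_set(utrs)
print(f"binding-site fraction among stabilized genes: "
      f"{dc.site_fraction(result.stabilized_genes, ann):.2f}")
```

prints

```
retained 218 of 500 genes after filtering
stabilized calls: 12 (planted: 12)
top-ranked gene G00367: rank metric 456.4, control t1/2 44.4 min, KO t1/2 >120 min, interaction p (GG) 6.54e-10
binding-site fraction among stabilized genes: 1.00
```

All 12 planted stabilized genes are recovered with no false positives. The
top gene's *apparent* control half-life (44 min) exceeds its generative one
(20 min) because the default simulation includes the fixed-depth
renormalization artifact, which inflates every curve; the knockout curve is
censored at the 120-min grid maximum, matching the ">120 min" reporting
convention. The rank metric is in percent-remaining units (knockout minus
control, averaged over 60 and 120 min). Every stabilized gene carries a
planted AU-rich site, so the site fraction is 1.00.

The same pipeline is available from the shell:

```sh
decaychase simulate --seed 7 --out-dir sim/
decaychase screen --counts sim/counts.tsv --annotation sim/annotation.tsv \
    --samples sim/samples.tsv --utrs sim/utrs.fasta \
    --control control --ko ko --out-dir screen_out/
decaychase scan --fasta sim/utrs.fasta --out-dir scan_out/
```

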