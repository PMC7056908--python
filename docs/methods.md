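# Methods

`riqtl` re-implements, as a tested pipeline, a systems-genetics analysis of
optic-nerve (ON) axon necrosis in the BXD recombinant-inbred (RI) mouse
family: strain-level aggregation of axon counts, heritability, winsorization
of outlier strains, genome mapping by Haley-Knott (HK) regression and by a
kinship-corrected linear mixed model (LMM), cis-eQTL classification of
positional candidates, a seven-criterion triage cascade, GO
cellular-component over-representation of correlate networks, and a
cross-trait comparison against intraocular pressure (IOP). Because the real
data live on GeneNetwork and are not bundled, the package ships a synthetic
RI-panel generator that reproduces the statistical structure every stage
assumes; the analysis drivers, tests and the acceptance script run entirely
on it. Readers for the real export formats (.geno, trait TSV, expression
TSV) are included for users who download the data themselves.

## Phenotype model

Each animal contributes a minimum of 12 counting fields of 7.49 x 7.49 um
spaced across one ON cross-section. The per-nerve count is
`round(total field count / sampled area x nerve area)`; density is reported
per um^2. Strain summaries are mean +/- SEM over replicates (SEM absent at
n = 1).

Heritability uses the one-way ANOVA decomposition across strains:
`Ve = MS_within`, `Va = (MS_between - MS_within)/n0` clamped at zero, with
the unbalanced-design coefficient `n0 = (N - sum n_i^2 / N)/(k - 1)`.
Two ratios are reported: the conventional intraclass `h2 = Va/(Va + Ve)`
and the strain-mean version `h2_RIx = Va/(Va + Ve/n_bar)` with `n_bar` the
harmonic-mean replicate count — the quantity relevant when mapping is done
on strain means, since averaging replicates shrinks the environmental
variance. `h2_RIx -> h2` as `n_bar -> 1` and is monotone in `n_bar`; both
are tested properties. Strains with a single animal stay in the between-strain
sum of squares and contribute zero within-strain degrees of freedom.

Winsorization follows the unit-step rank rule inferred from the published
replacement pairs: the k flagged high strains become `max(retained) + 1, +2,
..., +k` in ascending raw order, and flagged low strains `min(retained) - 1,
-2, ...` in descending raw order. This reproduces all four printed
replacements given the retained extremes they imply (3,733 and 617). Note
the source reports the low strain's raw value as both "276" (Results) and
"376" (Methods), and the highest strain as both "4,122" and "5,825"; we use
the Methods values in worked examples and do not attempt to reconcile the
discrepancy. Outlier *detection* is automated here as a Tukey fence
(1.5 x IQR) because the original selection was by inspection; the fence is
a default, and outlier lists can be supplied explicitly.

Sex is compared by a Welch (unequal-variance) two-sample t-test — the
pooled-variance choice is not specified in the source, and Welch is the
safer default — either on animals or on within-strain sex means restricted
to strains with >= 2 animals of each sex. Age enters as an OLS regression of
count on months beyond 13 (log-age offered); both checks exist to justify
mapping *unadjusted* strain means.

## Mapping

Dosage codes homozygotes 0 (B) and 2 (D) so the regression slope is the
per-allele effect; heterozygous and unknown calls are missing, not 1,
because RI strains are nominally homozygous. Between typed markers the
expected dosage conditions on both flanks through a two-state Markov step
whose switch probability is the sib-mated RI map expansion
`R = 4r/(1 + 6r)` of the Haldane fraction `r = (1 - e^(-2d/100))/2`. The
same R drives the genotype simulator, so simulator and mapper share one
recombination model by construction.

HK regression reports `LRS = n ln(RSS0/RSS1)` (LOD = LRS/2ln10), the
GeneNetwork scale on which the published thresholds are quoted. Scans
evaluate all typed markers plus a 1-cM pseudomarker lattice. Genome-wide
thresholds are empirical quantiles of the permuted max-LRS distribution —
significant at genome-wide p = 0.05 and suggestive at p = 0.63 (one false
positive per genome expected). Permutations shuffle strain means, matching
what is mapped. Localization uses bootstrap resampling of strains (argmax
tally; ties break to the lowest genomic coordinate) and a 1.5-LOD-drop
support interval; the interval rule is our choice, as the source states its
109–112.5 Mb interval without naming one.

The LMM is GEMMA-like: `y = mu + x b + u + e`, `u ~ N(0, sg^2 K)` with
`K = Z Z'/p` over column-centered 0/2 dosages of MAF > 0.05 markers,
leave-one-chromosome-out (LOCO) by default. Per chromosome, K is
eigendecomposed once and the data rotated; the variance ratio
`lambda = sg^2/se^2` is profiled by bounded scalar search on log10(lambda)
in [-5, 5] and re-optimized under both null and alternative; the per-marker
statistic is the likelihood ratio `2(l1 - l0)`. With K = I the model
provably collapses to OLS, a tested identity. Missing dosages are
mean-imputed inside kinship and LMM marker vectors (they are dropped
position-wise in HK); the simulator emits no missing calls, so this path
matters only for real data.

A robustness suite re-runs the scan under the three published outlier
treatments — raw, winsorized, censored — and reports the peak per scenario.

## eQTL classification and triage

Probe-level rules: a probe is *eligible* when its hybridization target is
SNP-free (a boolean annotation input; the original BLAT verification is out
of scope), and *detected* when its strain-mean log2 expression is >= 6.8
(boundary inclusive; a max-across-strains option exists). Each probe is
scanned as a microtrait (HK at typed markers); a gene is *cis*-modulated
when the peak lies on its own chromosome within 5 Mb of the gene start —
reading "a 10 Mb window of its position" as total width; the half-width is
configurable because the phrasing is ambiguous — and the peak LRS reaches
the probe's own suggestive threshold. Per-probe suggestive thresholds are
computed with a shared-permutation vectorized null: the null is exchangeable
over strains, so one set of strain permutations serves every probe and the
per-probe genome-wide max-LRS quantiles remain exact in distribution.

The triage cascade evaluates, per interval gene: (1) positional (gene start
in the closed interval), (2) cis in retina and/or eye, (3) membership of the
top-N trait correlates by |r| (sign-blind; ties by probe id), (4) detected,
(5) has a SNP-free probe, (6) harbors a nonsynonymous SNP, indel or
transcript variant, (7) network plausibility. Probe-mediated criteria
(2, 3, 4) are satisfied if *any* SNP-free probe of the gene satisfies them
in either tissue. Tier 1 = all seven; tier 2 = exactly one failure; a
relaxed mode waives cis. Criterion 7 is an explicit operationalization of a
qualitative judgment: the gene's detection-filtered top-correlate set is
tested for GO cellular-component over-representation (upper-tail
hypergeometric against the expressed background, BH FDR across terms), the
significant terms with no significant descendant ("terminal branches") are
kept, and the criterion passes when any terminal term name matches a
configured keyword set (default `mitochondri*`, `axon*`, `cytoskelet*`).
The background is the detection-passing platform content, not the genome,
because correlate sets are drawn from expressed probes. The FDR < 0.05
significance rule is our choice; the source does not state its cutoff.

## The synthetic panel

Defaults are the study conditions: 75 strains; 19 chromosomes of 80 cM at
2 cM marker spacing with a fixed 2 Mb/cM physical scale; 1–10 replicate
animals per strain (ages uniform on 13–30 months, ~30% male); one planted
QTL of +380 counts per D allele at the chromosome-12 analog (112 Mb);
between-strain residual variance 305,600 and within-strain variance
650,000, chosen once from the closed-form relations so the locus explains
~20% of strain-mean variance and conventional heritability sits in the
mid-30s; a +34 counts/month age slope; three high and one low outlier
strain (the winsorized pattern); and an IOP-like second trait planted at
r = -0.296 with the necrosis strain values. Strains are simulated directly
as two-state Markov mosaics with the RI-expanded switch probability rather
than via breeding generations — the marginal structure the mapper uses, at
a fraction of the cost. Counts are truncated (not re-drawn) at zero, which
preserves the mean structure at the price of a small bias for very low
strains; per-field Poisson sampling over 12 fields adds roughly 0.18e6 of
within-strain variance on top of the configured component, so the
field-level plug-in heritability truth is slightly optimistic (recovery
tests disable field sampling to keep the truth exact).

Expression (2,000 probes per tissue, retina and eye) plants: 156 interval
genes; 12 cis genes in the interval (log2 effect 0.5/allele), of which the
first is the causal gene (strong cis, in the trait module, protein-altering
variants, clean probes), one is a Wdr25-analog (below), three lack
variants, three have only SNP-overlapping probes, two sit below detection,
and two more pass everything — like the study, several genes legitimately
survive all criteria; a 60-gene trait module loading on the standardized
strain genetic value at rho = 0.6, 85% of it annotated to an "axon" GO leaf
under "neuron part" (exercising the terminal-branch rule); and GO decoy
terms (mitochondrion, nucleus, membrane) over non-module genes.

The Wdr25-analog is built to be strongly cis yet outside the top trait
correlates: its expression is driven by its own marker's *innovation* — the
residual of its local dosage on the trait-QTL dosage and the trait latent —
plus its own trait-independent 25-gene co-expression module (also
axon-annotated, so the network criterion can pass). There is an intrinsic
ceiling here: inside a 1.75-cM interval any trait-orthogonal cis signal
retains only ~26% of the local dosage variance, so its cis peak competes
with the genome-wide null maximum and the full "fails only correlation"
pattern reproduces in roughly 70–80% of seeds (the regression test pins a
seed; the quantified truth-recovery property concerns the causal gene,
which is recovered in 20/20 panels).

Because the simulated platform has 2,000 probes against ~45,000 on the real
arrays, the demo triage uses top-100 correlate lists (and top-200 for the
cross-trait comparison) to preserve the ~2–5% selectivity of the published
top-1,000/top-2,000 rules; both counts are configuration, not code.

Everything is keyed to a single integer seed: fixtures are bit-identical
across runs, and the pipeline manifest records config, seeds and SHA-256
digests of every output so reruns are verifiable.

## What passing tests do and do not show

The generator matches the *statistical* structure the pipeline assumes —
biallelic homozygous mosaics with map-expansion linkage, strain-structured
counts, planted cis effects and modules — not real BXD data: no genotyping
error, no heterozygous residue, no X-chromosome dosage, no epistasis,
uniform marker spacing, one probe per gene (two for the causal gene), a toy
GO vocabulary, and a linear cM→Mb map. Passing tests therefore demonstrate
that the estimators are correct and calibrated under the assumed model and
that the cascade recovers planted truth; they do not certify performance on
real arrays or real genotype files. Sizes used by the checked properties:
200 null panels (200 permutations each) for threshold calibration, 50
panels for parameter recovery, 20 panels for triage truth recovery —
chosen as the smallest sizes at which the binomial/recovery bounds are
meaningful.

## Numerical choices

LOD = LRS/4.60517 to 1e-9; argmax ties break to the lowest genomic
coordinate; monomorphic positions score LRS 0; zero-variance probes are
excluded from correlate ranking with a logged count; the kinship matrix is
validated symmetric PSD within 1e-8; eigenvalues are clipped at zero before
rotation; lambda search tolerance is 1e-7 on log10(lambda); per-nerve
counts round half away from zero; gene identity for cross-trait
intersections is case-insensitive symbol; intervals are closed on both
ends, and the 5 Mb cis window boundary is inclusive.
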