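# Methods

This note documents the models, numerical choices and design decisions
behind `glioconn`, and what the synthetic validation does and does not
establish about real data.

## Parcellation and compartments

The package operates on a fixed parcellation with 1-based region labels.
The default atlas has 246 regions in the Brainnetome-style layout where odd
labels are left-hemispheric and even labels right-hemispheric; a user atlas
CSV may override the hemisphere column for non-default parcellations. Every
unordered pair of distinct regions belongs to exactly one of three edge
compartments (intra-left, intra-right, interhemispheric); the three
partition the $R(R-1)/2$ pairs, with $123 \cdot 122/2 = 7503$ pairs per
hemisphere and $123^2 = 15129$ interhemispheric pairs at $R = 246$.

The default-mode-network (DMN) restriction is supplied through the atlas
file's `dmn_member` column. The packaged default flags the middle temporal
gyrus block (ids 81–88), the inferior parietal lobule (135–146) and the
cingulate block containing the anterior and posterior cingulate subregions
(175–188) — 34 regions, 17 per hemisphere. The literature names the
temporal DMN node the *middle* temporal gyrus; since subregion membership
is configurable, substituting any other hub definition is a one-column
edit, not a code change.

## Connectivity construction

**Edge weight.** $\mathrm{EW}_{ij} = N_{ij} / \tfrac12 (S_i+S_j)$, with
$S_i$ the row sum of the streamline-count matrix (each streamline counted
once per endpoint region). Since $S_i \ge N_{ij}$ and $S_j \ge N_{ij}$, the
denominator is at least $N_{ij}$, so $\mathrm{EW} \in [0,1]$; the formula is
invariant to uniform rescaling of counts. Isolated region pairs
($S_i + S_j = 0$) receive EW 0 with a logged warning.

**FC.** Zero-lag Pearson correlation of regional time series ("cross-
correlation" in the lagged sense is never computed; the Fisher-z step
presupposes a correlation coefficient). $r$ is clamped to
$\pm(1 - 10^{-12})$ before `atanh` so degenerate (identical) series cannot
produce infinities; clamping is logged. Regions with zero temporal variance
yield missing rows/columns with a warning rather than NaN propagation.

**Edge mask.** An edge is analysis-eligible iff every control subject has
at least one streamline on it — the stricter of the two plausible readings
of "connected in controls", chosen because it is operationally unambiguous.
The mask is built once from controls and applied identically to all
subjects and all three modalities.

## Summaries, relabelling, outliers

Compartment means are unweighted over masked-in, defined edges. An FA edge
inside the mask but absent in an individual subject is *omitted* from that
subject's FA mean (FA of no fibers is meaningless) while the corresponding
EW contributes its formula value 0; contributing-edge counts are reported
beside each mean, and a fully empty compartment is an error, never a silent
gap.

Patients' left/right means become ipsi-/contralesional by lesion side;
controls receive the left/right average as both ("healthy baseline"). For
the coherence profiles, controls are analyzed on their raw left/right means
(profiles are reported as LEFT/RIGHT for controls), patients on
ipsi/contra; both views run through the same machinery.

Outlier correction is a single pass per group and variable: values more
than 2.5 sample standard deviations (strict inequality, $n-1$ denominator)
from the group mean are replaced by the most extreme surviving in-group
value in the same direction — a nearest-rank winsorization, which is one
reading of replacing by the "worst" group score; statistics come from the
uncorrected data and the pass is not iterated. Replacements never widen the
group's range and are reported as flags. Simulation shows the step does not
distort type-I error at the cohort's group sizes.

## Inference

**MANOVA.** Pillai's trace $V = \mathrm{tr}(H(H+E)^{-1})$ from the
between/within SSCP decomposition, with the standard F approximation: for
$g$ groups, $p$ DVs, $N$ observations, $s = \min(p, g-1)$,
$m = (|p-g+1|-1)/2$, $n = (N-g-p-1)/2$,
$F = \frac{2n+s+1}{2m+s+1}\,\frac{V}{s-V}$ on
$\big(s(2m+s+1),\, s(2n+s+1)\big)$ df. For the study's design ($g=3$,
$p=3$, $N=56$) this yields df (6, 104) — which identifies Pillai as the
reported statistic, since the Wilks/Rao approximation would give
df2 = 102. Wilks' lambda is carried as a clearly labelled secondary output.
A singular within-group SSCP raises an informative rank-deficiency error.

**Univariate follow-ups and post-hocs.** Classical one-way ANOVA
(df $g-1$, $N-g$); pairwise t-tests share the pooled ANOVA error variance
(error df $N-g$) with two-sided p-values multiplied by the number of pairs
and capped at 1 — the SPSS-style "Bonferroni" post-hoc. Follow-ups are
computed unconditionally and *flagged* by whether the omnibus passed, so
hierarchical reporting never hides results.

**Partial correlation.** Both variables are residualized on an intercept
plus covariates by least squares; the Pearson correlation of the residuals
is tested with $t = r\sqrt{\mathrm{df}/(1-r^2)}$, $\mathrm{df} = N - 2 - k$,
two-sided. With $k=0$ this is exactly the plain Pearson test. The same df
convention lets significance be recomputed from a reported $(r, n)$ pair
alone (`partial_corr_significance`).

**Coherence profiles.** All 36 pairs of the 9 summary variables, age as the
covariate, judged at `alpha / family_size` with family size 9 — the
enumeration of the three compartments × three modalities, reproducing the
reported adjusted threshold of 0.006 at three decimals; the family size is
a config knob. Exactly 9 pairs are intramodal (3 per modality) and 27
intermodal. The dissociation summary counts significant intramodal pairs
split into structural (EW + FA, of 6) and functional (FC, of 3).

p-values are printed to 3 decimals in human-readable output and stored at
full precision in machine output.

## Synthetic cohort generator

The generator emulates the *derivatives* such a study consumes — counts,
FA edges, ROI time series, demographics — not raw imaging. Group sizes
(27/15/14), age distributions (46±14, 37±11, 65±8, truncated to [18, 80)),
sex ratios and lesion-side frequencies follow the study cohort. The edge
template has 619 left, 637 right and 92 interhemispheric edges — the
reported surviving-edge counts — with base Poisson rates of 15–45
(intra) and 45–75 (inter) streamlines.

Each subject carries a 3×3 grid of latent compartment targets

$$v = \mu + \delta + s\,(\lambda\, g_{\text{mod}} + \sigma_\epsilon \eta),$$

with per-modality standard-normal factors $g$ shared across the three
compartments. The three factors are mutually independent, so *intermodal*
correlations are null by construction: a coupled EW/FA factor would
contradict the observed null intermodal findings, which is why the
generator uses three factors even though EW and FA are both "structural".
Defaults: baselines $\mu$ of 0.06/0.02 (EW intra/inter), 0.45/0.48 (FA),
0.35/0.25 (FC Fisher-z); between-subject scales $s$ of roughly 10% of
baseline (EW inter 0.004, i.e. 20%, reflecting the high variability of
normalized interhemispheric streamline counts and the small 92-edge
compartment); loadings $\lambda = 0.8$ on all modalities for controls and
$\lambda_{EW} = \lambda_{FA} = 0$, $\lambda_{FC} = 0.8$ for patients;
residual noise $\sigma_\epsilon = 0.15$, chosen so a 0.8 loading implies
intramodal correlations near 0.9 — the magnitude reported for significant
pairs. Planted effects: interhemispheric EW −15% of baseline in both
patient groups, FA −0.03 ipsilesionally in IDHwt, FA +0.03 contralesionally
in IDHmut.

**Realizing EW targets.** Edge weight is scale-invariant, so block rate
scales alone cannot move the intrahemispheric EW *level*. The generator
therefore adds a diffuse background streamline field spread uniformly over
non-template pairs: it inflates region strengths (denominators) without
ever surviving the all-controls mask (per-pair background rates are kept
below ~1, making 27-subject co-occurrence vanishingly rare). Per subject,
the three block scales and the background strength are solved by a damped
multiplicative fixed-point iteration so the *expected* compartment EW means
equal the targets (the left scale is the gauge; the background update is
amplified by the inverse of its elasticity $b/(S+b)$). The expectation
accounts for the template-degree-dependent share of background each region
actually receives; residual realization bias is below 0.2%. Infeasible
targets (outside the template's achievable range) raise an error rather
than being silently clipped.

**FA and time series.** FA edges are normal around the compartment target
(sd 0.05), truncated to (0, 1), defined exactly where counts are positive.
Time series are $T$ iid draws from a two-factor Gaussian block model whose
within-left, within-right and between-hemisphere correlations equal the
tanh of the Fisher-z targets exactly; an infeasible between-block request
($|c| > \sqrt{a_L a_R}$) is repaired to the nearest feasible structure with
a logged warning. A single master seed spawns per-subject substreams
(`numpy.random.SeedSequence`), making cohorts bit-reproducible with
independent subjects.

**Reduced problem size.** The calibration suites run at 40 regions and 120
time points with a proportionally thinned template (60/62/20 edges). At
this size the per-edge normalized weight is intrinsically larger and the
246-region EW baselines would demand a background field strong enough to
leak into the edge mask, so the reduced preset raises the EW baselines to
0.12/0.04 (scales 0.006/0.003, interhemispheric effect −15% of the raised
baseline). The full-size defaults are the study conditions; the reduced
preset exists for Monte-Carlo throughput.

## What the validation shows — and does not

The simulation suite demonstrates that the pipeline (i) is calibrated: with
no planted effects and equal loadings, MANOVA and partial-correlation
rejection rates stay inside the 99% binomial band around 5% over 2000
reduced-size replicates run through the *entire* pipeline including outlier
correction; (ii) recovers the planted pattern at the study's size: the
ipsilesional FA and interhemispheric EW effects are detected in ≥80% of 50
seeded cohorts, control profiles show significant structural and functional
intramodal pairs, and patient profiles show zero significant structural
intramodal pairs with preserved functional ones in ≥90% of profiles. The
patient-profile criterion is evaluated per profile: with 6 structural pairs
tested at the 0.006 threshold, chance alone produces a spurious structural
pair in ≈3% of null profiles, an irreducible floor.

The generator does *not* emulate spatially structured tumor effects,
distance-dependent connectivity, head motion, physiological noise,
hemispheric asymmetries beyond edge counts, or any coupling between
structural and functional connectomes (intermodal coupling is null by
design). Passing these tests therefore shows the *analysis machinery* is
correct and well-calibrated under its stated model — not that the
biological conclusions transfer to any particular real dataset.

## Numerical choices

- Missing values are NaN throughout; matrices validate symmetry (including
  the missing pattern) and missing diagonals on construction.
- Correlation clamping at $1 - 10^{-12}$; TSV round-trips at `%.10g`;
  report JSON with sorted keys for byte-reproducibility.
- EW calibration: tolerance $10^{-4}$ on the target ratio, ≤80 iterations,
  damping 0.7, hard failure if the final expected means deviate >2%.
- Outlier correction requires ≥3 subjects per group and is skipped (not
  errored) for smaller groups, which only arise in toy inputs.
- Ages are drawn by rejection sampling from the truncated normals; the
  bounds [18, 80) mirror the inclusion criteria.
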