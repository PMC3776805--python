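# Methods

This note documents the statistical models, numerical choices, and known
limitations behind `refstab`. It is written for users who need to judge
what a passing test suite does and does not establish about their own data.

## Quantification model

Quantification cycles are treated as the primary measurement. Technical
replicates are averaged on the Cq scale (SD with the n−1 denominator;
a singleton replicate receives SE 0 with a logged warning) *before* the
exponential transform to relative quantities; averaging before
transformation keeps replicate noise symmetric on the scale where it
arises. Relative quantities use the per-assay efficiency,

RQ_gs = (1+E_g)^(Cq_g,cal − Cq_gs),

with the calibrator chosen per gene as the sample with the lowest replicate
mean Cq; ties are broken by lexicographic sample label so reruns are
deterministic. RQ is therefore bounded by 1 and equals 1 at exactly the
calibrator. Standard errors follow the delta method on the exponent:
SE(RQ) = RQ·ln(1+E)·SE(Cq). Normalization factors are geometric means of
reference RQs with relative errors combined in quadrature,
SE(NF)/NF = (1/f)·√Σ(SE(RQ)/RQ)²; NRQ errors combine the target's and the
NF's relative errors the same way. The rescaling constant (mean NRQ of the
chosen group) is treated as exact. Pfaffl ratios operate on group-mean Cq
values; per-sample ratios can be obtained by passing singleton groups.

Stability and NF computations require a complete gene × sample grid;
samples missing any gene are dropped with a logged list, because pairwise
log-ratios and geometric means are undefined on holes and silent imputation
would bias M downward.

## geNorm and qBase statistics

M values use base-2 logarithms. Any fixed base rescales all M values by a
common factor, so the ranking is base-invariant; base 2 makes "one unit of
M" correspond to ratio SDs measured in doublings. Sample SDs use n−1
throughout. Elimination recomputes M on the retained set each round and
removes the arg-max; exact ties are broken by gene label, with the later
label eliminated first, and every tie-break is logged. The final two genes
are reported jointly at rank 1 with their shared two-gene M — they are
mutually unresolvable by construction — and the next gene takes rank 3
(competition ranking). Any retained-set M above 1.5 (the algorithm's
conventional heterogeneity alarm) is flagged but does not stop the run.

The qBase CV of a candidate set normalizes each gene by the NF of the full
set *including the gene itself*, matching the convention of reporting one
mean CV per panel; consequently a single-gene set self-normalizes to CV 0,
and CV 0 for a multi-gene set occurs iff all members are mutually
proportional. Acceptability uses strict inequalities (M < 0.5, CV < 0.25);
a gene sitting exactly on a threshold is rejected, and the choice is
logged. Tissue panels should be analyzed separately — the digital screen's
omission analysis is the tool that justifies this — and the package never
pools panels implicitly.

## Amplification curves

The package estimates its own baseline as the mean fluorescence over
cycles 3–10 (instrument software normally does this invisibly; the rule
here is explicit and overridable). Cq is the linearly interpolated crossing
of baseline-subtracted fluorescence through the threshold (default 30 RFU,
applied after baseline subtraction). Linear interpolation is the
smallest-assumption crossing estimator; on noiseless exponential curves it
makes Cq exactly translation-equivariant in log template amount.

Efficiency fitting searches windows of 5, then 4, then 3 consecutive
cycles (more points preferred for slope stability) inside the exponential
phase, defined as baseline-subtracted fluorescence above 3× the baseline
noise SD and below 80% of the observed maximum. The first window size with
any OLS fit of log10 F on cycle reaching R² ≥ 0.998 wins, ties broken by
highest R²; E = 10^slope − 1, so the slope identity (1+E) = 10^slope holds
exactly in every accepted fit. Reactions with no qualifying window are
excluded from the gene mean rather than forced, and a per-gene mean E
outside [0.85, 1.10] — the span of acceptable assays — warns without
failing. Near the detection limit the log of noisy fluorescence is biased
downward (log-concavity), which inflates single-fit slopes slightly; the
per-gene mean over many reactions is the intended estimator and the
package's recovery tests measure exactly that quantity.

## Synthetic data

The Cq generator models three noise sources explicitly: per-sample loading
factors and per-gene biological noise are drawn on the log2-expression
scale and converted to cycles through log2(1+E) (so one doubling is one
cycle at E = 1 exactly), while replicate noise is additive Gaussian on the
Cq scale — the standard technical-noise model. Regulated genes follow a
geometric trend across ordered groups (fold^(k/(G−1))), the simplest
monotone profile; an optional explicit per-group fold vector covers
non-monotone cases such as a mid-series peak. Default noise levels
(loading SD 0.25, technical SD 0.15 cycles, biological SDs graded
0.05–0.4) are editorial choices representing a competent two-step RT-qPCR
workflow; the demonstration panel uses 4 stages × 4 biological samples ×
3 wells.

Curve simulation is a clipped exponential plus Gaussian read noise:
F_c = baseline + min(start·(1+E)^c, plateau − baseline) + ε. Defaults
(baseline 50 RFU, plateau 1200 RFU, start 10⁻³ RFU, 40 cycles) place the
threshold crossing near cycle 15 and give ≥ 6 clean exponential cycles.
There is no sigmoidal deceleration before the plateau clip, no
multi-component dye model, and no melt behaviour — so curve-level tests
validate the estimators' contracts, not instrument realism.

Count libraries are Poisson: reads ~ Poisson(N_l · p_u · mult_ul), with
stable unigenes defined by all multipliers equal to 1. The default screen
uses 8 libraries of 10⁵ reads (four bud, four fruit stages), 40 stable
unigenes at proportion 10⁻³, and 40 fruit-regulated unigenes with graded
1.5–6× multipliers. Real 454 data add overdispersion, assembly artifacts,
and mapping ambiguity that the Poisson model deliberately omits; the screen
is descriptive (no count-model testing), so these affect CV magnitudes but
not the package's arithmetic.

What passing tests show: the statistics are computed correctly (oracle
equivalence, closed forms, invariances) and recover known structure under
the stated noise model. What they do not show: robustness to RT
inhibition, pipetting outliers, inter-run drift, or non-Gaussian biological
variation — none of which the generators emulate.

## Digital screen conventions

CVs are computed on per-library proportions (count/total) rather than fold
values; the two are identical up to a common rescaling, and proportions
avoid any dependence on the reference library. Whole-library totals come
from metadata, not column sums, since retained unigenes are a subset of
each library. A zero count in the reference library leaves a fold profile
undefined: the unigene is flagged and excluded from CV summaries, while
zeros elsewhere give fold 0 and stay in. ΔCV is defined as CV after
omission minus CV over all libraries, so "decrease" literally means the
unigene looks more stable without the omitted series. Both present-filter
phrasings in circulation — at least k detected libraries, and at least r
reads in every library — are implemented as explicit modes with neither
privileged.

## QC gates

The 3′:5′ integrity ratio uses a fixed comparative-Cq amplification factor
of 2 by default, with an override to use a measured (1+E); the 4.43-fold
failure cutoff is a configurable constant adopted from practice rather
than re-derived here. Range gates stated as "between" are inclusive;
">" gates are strict; a missing Cq fails the integrity gate closed. Leaves
use the floral-bud purity band. No gel, RIN, or genomic-contamination
interpretation is attempted.

## Numerical and I/O choices

All writers emit 12-significant-digit decimals, making write/read round
trips lossless below 1e-9 while staying diffable. Long (tidy) CSV is the
canonical Cq format because replicates and group metadata attach naturally.
Every CLI run logs its thresholds, seed, dropped samples/genes, and
tie-break events, so any result can be replayed exactly. The acceptance
script's problem sizes — 200 stability panels, 50 curve seeds × 6 reactions
per efficiency, one 80-unigene count panel, 25 peak-shift scenarios — are
chosen to make the Monte-Carlo summaries stable to well under their
assertion margins.

## Known limitations

- No inter-run calibration, absolute quantification, or dilution-series
  (standard-curve) efficiency estimation.
- geNorm's pairwise-variation cutoff for the optimal *number* of
  references (V_{n/n+1}) is out of scope; set adequacy is argued through
  the NF-comparison and peak-shift analyses instead.
- Alternative stability algorithms (NormFinder, BestKeeper) are not
  implemented.
- The estimator classes validate inputs but do not accept sparse matrices
  or missing values; completeness is a hard requirement by design.
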