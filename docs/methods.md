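# Methods

This note documents the models behind `ctdnamrd`: what each stage
assumes, which parameters matter, how the synthetic cohort is
calibrated, and what the simulations can and cannot establish.

## ddPCR partition model

A reaction converts 20 µL of a 22 µL mix into droplets of 0.834 nL;
droplet counts per well are drawn Normal(16 948, 1852) in simulation,
matching a QX200-class reader. Template molecules are assigned to
droplets uniformly at random, so occupancy is multinomial and the
positive-droplet fraction follows the Poisson partition law
`P(positive) = 1 − e^(−λ)`. Concentration estimation inverts this:
`λ = −ln(1 − k/n)`. Saturated wells (`k = n`) are rejected rather than
assigned infinite λ; the two-channel assay makes saturation observable
rather than silent.

Amplitudes, when simulated, come from three Gaussian clusters (empty,
wild-type-positive, mutant-positive). This is the minimal structure
that exercises thresholding; real droplet "rain" (partial
amplification) is deliberately out of scope, so amplitude-based tests
demonstrate threshold mechanics, not robustness to rain. The threshold
sits `k` SDs (default 3) below the positive-control positive cluster's
mean amplitude, with positives counted at or above threshold. A
control whose amplitude cloud is not clearly bimodal (cluster
separation below 3 combined SDs) is rejected as uninformative.

DNA input is accounted in haploid genome equivalents (GE, 3.3 pg), so
66 ng ≈ 20 000 GE. The GE actually screened by a merged sample is
recovered from the pooled wild-type channel by the same partition math
(one wild-type locus copy per haploid GE), because the noise callers
normalise by DNA analysed, not by pre-PCR quantification.

### Eluate accounting

cfDNA from 8 mL plasma elutes in 60 µL; the protocol books 54 µL for
ctDNA analysis and 4 µL for quantification (the 2 µL discrepancy is the
protocol's own and is left unreconciled — both volumes are plain config
fields). A DNA-sparing two-step strategy applies to a configurable
fraction of samples (default 105/373): 18 µL analysed first, positives
stop there, negatives get the remaining 36 µL with all wells merged.
The fraction of extracted DNA a call rests on — eluate fraction times
the 20/22 dropletised fraction — divides into the per-mL level, so the
two-step route changes precision, not calibration. Eluate is split at
9 µL per well, with extra wells added if a sample's expected wild-type
load would push a well past λ ≈ 1.3.

## Noise profiles and the four callers

Every assay has a blank panel: false-positive mutant counts on 94
tumour-free buffy-coat samples at log-normally varied DNA inputs
(median 10 000 GE). Blank counts are simulated Poisson at the assay's
chemistry noise rate (default 1e-5 false events per GE, a typical
hotspot-assay background). The four callers deliberately differ in how
they generalise from the panel:

* **poisson** — pooled panel rate × sample GE gives the expected noise
  `μ`; `p = P(X ≥ k | Poisson(μ))`.
* **dynamic LOB** — each blank count is rescaled by (sample GE / blank
  GE); the limit of blank is the empirical 95th percentile of the
  rescaled counts; positive only on strict excess, so an exactly-LOB
  count stays negative (conservative tie-break).
* **castle-style** — negative-binomial regression of blank counts on a
  constant with log-GE exposure. The NB dispersion absorbs
  between-blank rate variation; when it is unidentifiable (all-zero or
  equidispersed panels) the model collapses to Poisson and the result
  is flagged. This caller also supplies the error-corrected count
  `max(0, k − μ̂)`, which becomes the reported level.
* **alpaca-style** — beta-binomial on the mutant droplet fraction with
  beta parameters moment-matched to the blank fractions; degenerate
  moments reduce to a binomial tail.

These four are stand-ins that preserve the documented character of the
published methods of the same names (error-regression vs limit-of-blank
vs Poisson vs fraction-based); they are not re-implementations of the
original code. Per-caller alpha defaults to 0.05: the consensus rule
(≥ 3/4, ties to the castle-style caller), not alpha, is the primary
specificity mechanism. Noise correction is applied after merging
reactions; correcting per well and summing would subtract the same
expected noise, differing only through the clamp at zero.

Per-profile model fits are memoised (profiles are immutable), which is
what makes cohort-scale simulation cheap.

## Multitarget model

Sequencing reads are collapsed to molecules: with > 100 000× raw
coverage the molecule, not the read, is the information-bearing unit,
so per-target detectability defaults to 1.0 and lower values model
library-conversion loss if wanted. Extracted GE is cfDNA × 8 mL; the
library cap (20 000 GE) admits only `input/extracted` of the plasma's
molecules, which is the mechanism that penalises the multitarget route
precisely in high-cfDNA (typically preoperative) samples. Per-target
mutant molecules are Poisson with mean
`ctDNA × plasma × input_fraction × detectability`; background molecules
add at 3e-6 per GE per target. A target detects when its count clears a
Poisson tail test at per-target alpha 1e-3 (at ~14 000 GE input this
means ≥ 2 molecules); the ≥ 2-of-16 rule then gives an analytic blank
positivity of `1 − (1−p)^16 − 16p(1−p)^15`, well under 1 % at the
defaults. The level is the mean of molecules/mL over all 16 targets
including zeros: in the sub-molecule regime this estimator shrinks
toward the true level, whereas a single-target assay that detects at
all must report at least one-fragment quanta — the mechanism behind
single-target-only positives showing higher apparent levels.

## Synthetic cohort

The generator emulates a stage II–III colorectal surveillance study:

| parameter | default | basis |
|---|---|---|
| patients | 112 (23.2 % stage II) | study composition |
| recurrence fraction | 0.24 | 27/112 |
| time to recurrence | log-normal, median 12.2 mo, σ_log 0.25 | printed median/IQR |
| follow-up | Normal(35.8, 0.7) mo | printed median/IQR |
| adjuvant treated | 70.5 %, months 2–6 | study composition |
| draw availability | preop 0.82, postop 0.50, serial 0.58 | 92/112, 56/112, 65/112 sub-cohorts |
| serial draws | every 3 mo after definitive therapy, max 3 | 124 serial samples / 49 patients |
| cfDNA | log-normal median 1650 GE/mL, σ_log 0.6; preop ×1.6 | extracted-GE medians ≈ 12–14 k GE; preop draws engage the 20 k cap |
| preop ctDNA | log-normal median 1.0 GE/mL, σ_log 2.0 | preop detection ~80–95 % |
| postop residual | log-normal median 0.08 GE/mL, σ_log 2.0 | postop detection ~50 %; discordant levels ~0.2–1 GE/mL |
| doubling time | log-normal median 1.5 mo, σ_log 0.3 | ~4–7 mo lead before a 12-mo recurrence |
| biological draw noise | σ_log 0.3 | plausible within-patient variation |

Residual disease grows exponentially after surgery (`residual ×
2^(t/doubling)`) for recurrence patients; a small fraction (6 %) of
non-recurrence patients carry residual disease that adjuvant treatment
clears at its start. Radiological recurrence time is drawn directly
rather than derived from the trajectory crossing an imaging threshold —
simpler, and sufficient for lead-time logic. Both assay aliquots of a
draw share one (cfDNA, ctDNA) realisation; all randomness flows from a
single generator per run, so a seed reproduces a cohort byte-for-byte.

What the simulator does **not** model: CHIP and germline contamination,
assay dropout, FFPE artefacts, imaging schedules, competing risks, and
any correlation between cfDNA level and tumour burden. Passing
cohort-level tests therefore shows that the pipeline's comparative
logic behaves as designed under the study's sampling conditions — not
that either assay would achieve these operating points on real plasma.

## Statistics layer

Fisher's exact test uses the sum-of-small-probabilities two-sided
convention (the convention of the dominant statistical environments).
Wilcoxon tests use midranks, dropping zero differences, with exact
small-sample nulls where tie-free. Wilson intervals come from the score
formula; boundary cases (k = 0, k = n) pin to 0 and 1 exactly.
Day-to-month conversion, where needed, uses 30.44 days/month. The
time-dependent Cox model represents ctDNA as a start-stop covariate
switching 0 → 1 at first detection, maximised with Efron tie handling;
monotone-likelihood fits (no events on one covariate arm) surface as
huge hazard ratios with unbounded Wald intervals rather than errors,
and the cohort pipeline applies a small ridge penalty (0.1) to keep its
reported ratios finite. Patients never positive, or positive only
after their event time, contribute a single unexposed episode.

## Problem sizes and numerical choices

Monte-Carlo checks use 10 000 wells for estimator bias (|relative
bias| < 1 % at λ ≤ 1), 2000 blank samples per caller for specificity,
10 000 blanks for the ≥ 2-of-16 analytic check, 200 replicates for Cox
CI coverage, and 50 cohort replicates for the comparative findings —
sizes chosen so sampling error is comfortably below the effects being
asserted while a full run stays in the minutes range on one core.
Enumeration oracles (hypergeometric tables, rank permutations, partial-
likelihood grid search) back the exact tests at small n. Degenerate
inputs follow one rule throughout: impossible requests raise
(`k = n` wells, empty merges, non-positive levels in log–log fits),
while uninformative data return the uninformative answer (empty
amplitude lists, all-zero paired differences).

## Known limitations

The four callers are declared stand-ins, so absolute sensitivity
differences between them should not be read as statements about the
published algorithms. The cohort's comparative findings are
directional by construction: the study's patient-level counts (e.g.
exact hazard ratios or the 72/92-vs-88/92 preoperative split) depend on
its actual per-sample data and are not reproduction targets. The MT
background model is per-target-homogeneous; real panels have
target-specific error spectra.
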