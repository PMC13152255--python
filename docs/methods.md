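# Methods

## Point-based classification

Evidence tokens follow the grammar `FAMILY NUMBER [_P|_M|_S|_VS]` with
families PVS/PS/PM/PP (pathogenic) and BA/BS/BP (benign).  An explicit
suffix sets the applied strength; otherwise the family default applies
(PVS very strong; PS/BS strong; PM moderate; PP/BP supporting).
Strength converts to |points| 1/2/4/8, signed by direction, and the
aggregate maps onto PV ≥ 10, LPV 6–9, VUS −1–5, LBV −6–−2, BV ≤ −7 —
bands that partition the integers, so classification is total and
monotone.  Two conventions close gaps the scheme itself leaves open:

* **Duplicate families are rejected.**  Applying `PS3` and `PS3_P`
  together would count one criterion twice; the aggregator raises
  instead of summing.
* **BA1 short-circuits.**  The stand-alone benign criterion has no point
  value here.  When present, the variant is labelled BV outright, the
  result flags that the short-circuit fired, and BA1 contributes nothing
  to the total.  This preserves the usual stand-alone semantics without
  inventing a point weight.

Trailing parenthetical annotations on tokens (`BP7_S (RNA)`) are
accepted and ignored; they record the assay behind a call, not its
arithmetic.

## SGE functional-evidence integration

Each screen's seven categories carry points +4/+2/+1/0/−1/−2/−4; the
sign is the binary functional call.  Integration rules:

* both calls pathogenic → PS3-family code; both benign → BS3-family;
* assigned strength = the larger |points| of the pair (4 strong,
  2 moderate, 1 supporting), so a (+4, +2) pair yields full-strength
  PS3 while a (−1, −1) pair yields the downgraded BS3_P;
* opposite signs, or exactly one uncertain call, are **discordant**: no
  evidence is assigned;
* two uncertain calls are **uninformative** — distinguished from
  discordant because nothing about the pair is contradictory; such pairs
  are excluded from discordance statistics.

The max-strength rule is symmetric in the two datasets and monotone:
strengthening either input never weakens the assigned code.  Integration
refuses code sets that already contain a PS3/BS3-family code.

## Multifactorial likelihood

`posterior = prior·LR / (prior·LR + 1 − prior)` at full floating-point
precision; reporting rounds to three decimals.  The combined LR is a
plain product of non-negative components (empty product = 1).  The only
rejected input is the indeterminate prior 1 with LR 0.

IARC bands: class 1 p ≤ 0.001; class 2 0.001 < p < 0.05; class 3
0.05 ≤ p < 0.95; class 4 0.95 ≤ p ≤ 0.99; class 5 p > 0.99.  The
published band edges are ambiguous at printed precision (a posterior
displayed as 0.001 can denote a value just below it); placing 0.001 in
class 1 makes the ladder exhaustive, disjoint and consistent with every
classified fixture row.  The LR exclusion window [0.5, 2] is inclusive
at both ends — the conservative reading, excluding more borderline
variants.  Window bounds and the prior table are configuration
(`PipelineConfig` / YAML); the shipped priors mirror the magnitudes of
published BRCA2 prior tables (C0 0.02 … C65 0.81; truncating types
0.96) but carry no authority — curation against a specific database
should supply that database's priors.

## Agreement statistics

Clinical classifications collapse to three sides: pathogenic (PV/LPV,
IARC 4–5), uncertain (VUS, IARC 3), benign (LBV/BV, IARC 1–2).  Major
error: definitive side vs opposite call.  Minor error: definitive side
vs uncertain call, or uncertain side vs definitive call.  Percentages
are reported to one decimal, rounded half away from zero; counts are
kept internally.

The Bhapkar statistic on a k×k paired table with proportions
`p_ij = n_ij/n` uses `d_i = p_i· − p_·i` (i = 1..k−1) and covariance
`v_ii = p_i· + p_·i − 2p_ii − d_i²`, `v_ij = −(p_ij + p_ji) − d_i d_j`;
the statistic `n·dᵀV⁻¹d` is referred to χ²(k−1).  Degenerate inputs:
a singular V falls back to the Moore–Penrose generalized inverse with
df = rank(V); V = 0 with d = 0 returns statistic 0, p = 1 (homogeneity
holds trivially); V = 0 with d ≠ 0 returns +∞, p = 0 (complete
asymmetry).  The implementation is cross-checked in the tests against
the k = 2 closed form, against statsmodels' independent implementation,
and against a multinomial parametric bootstrap under the symmetrized
null (10,000 replicates; agreement within Monte-Carlo error, tolerance
0.02 ≈ 4 standard errors at p = 0.5).

## Synthetic cohorts

The generator draws, per variant: a true class from a five-tier mixture
(default 0.15/0.10/0.40/0.20/0.15 for PV/LPV/VUS/LBV/BV, weighted toward
VUS as in clinical referral series); an evidence set rejection-sampled
from the code families used in BRCA2 curation practice (PVS1, PS1, PM2,
PM5, PP1, PP3, BS1, BS2, BP4, BP7 — PS3/BS3 are reserved for the
integration step) until the point total lands in the true class's band
(PV capped at 24 and BV at −12, the range the pool can produce);
a paired SGE result; and LR components.

SGE pairs: with probability `sge_discordance_rate` (default 0.169, the
fraction of assayed variants on which the two published screens
disagree) the pair is forced discordant by flipping one dataset's sign
or dropping it to uncertain with equal probability — the two discordance
modes seen in real data.  Otherwise both categories take the truth's
sign (uncertain for VUS truth), each dataset independently sign-flipped
with probability `sge_error_rate` (default 0.1).  Corruption therefore
also creates *incidental* discordance at rate ≈ 2·e·(1−e); analyses that
recover one injected rate set the other knob to zero.

LR components are lognormal — positive, multiplicative, and skewed like
real likelihood ratios — with log-mean ±0.6 and log-sd 0.4 by default
(three components per variant), giving near-complete separation of the
pathogenic and benign groups at LR = 1 (normal-tail bound ≈ 0.995).
VUS-truth variants draw their group fairly at random.  None of this is a
claim about any real cohort's LR distribution; it is a test harness.

What the simulator does **not** emulate: linkage between evidence codes
and the SGE result for the same variant, pedigree structure behind the
LR components, per-variant allele frequencies, or assay-specific failure
modes.  Passing recovery tests therefore demonstrates the pipeline's
arithmetic and bookkeeping, not clinical validity on real data.

## Problem sizes and determinism

The fixture analyses are exact and instantaneous (13 and 29 variants).
Simulation-based tests use cohorts of 200–1,000 variants, recovery
checks use exact binomial 99% intervals, and the bootstrap calibration
uses ten 3×3 tables of n = 2,000 with 10,000 replicates — sizes at which
the chi-square asymptotics they probe are expected to hold.  All
randomness flows from explicit seeds (`numpy.random.default_rng`);
identical seeds give byte-identical cohorts and reports.

## Known limitations

* HGVS strings are opaque identifiers; no transcript-aware validation
  or normalization is performed.
* The pipeline assigns at most one functional code per variant and does
  not model evidence interactions beyond point addition.
* LR components are taken as given (or simulated); estimating them from
  clinicopathological records is out of scope, as is computing
  Align-GVGD grades or SGE function scores themselves.
* The Bhapkar p-value is asymptotic; on very small tables (the 13- and
  5-variant fixtures) it is reported as computed, and the bootstrap
  cross-check covers only moderate-size tables.
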