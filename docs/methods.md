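# Methods

This note documents the scoring model, the default parameter table, the
synthetic-cohort generator and the numerical choices the package makes
where the instrument's published description leaves the design open.

## The scoring pipeline

**Rescaling.** Each of the 47 items carries an integer threshold
N ∈ {2,…,6} splitting the 1–9 rating scale into a healthy and a
clinical-risk side: problem items rescale as `N − rating`, spectrum items
as `rating − N`. A rescaled value below zero is, by definition, a severe
response; the DSM-5 mapper uses exactly the same cut, so "severe symptom"
and "negative rescaled value" are one concept computed one way
(`is_severe(r, item) ⇔ rescale_item(r, item) < 0`, enforced by test over
all 423 rating×item pairs).

**Negative weighting.** The instrument applies a differential, nonlinear
amplification to negative rescaled values so that graver symptoms dominate
the sum; the published description fixes the *orderings* (item-severity
differential at equal rescaled value; superlinear growth toward the
extreme) but not the functional form. This package realizes it as a
per-item power law, `v = −w·|x|^γ` for `x < 0` (identity for `x ≥ 0`),
with weight `w > 0` and exponent `γ ≥ 1` stored per item in the
configuration. The power law is the simplest two-parameter family
producing both orderings; any alternative monotone form can be substituted
by editing the config (γ = 1 recovers linear weighting) or swapping
`weight_matrix`. Positive values are never reweighted.

**Normalization.** The intermediate sum S is mapped onto the reporting
scale by two linear segments anchored at the bank's *theoretical*
extremes: `S ≥ 0 → 200·S/S_max` and `S < 0 → −1 − 99·S/S_min`, giving
MHQ(S_max) = 200, MHQ(S_min) = −100, MHQ(0) = 0 and MHQ(0⁻) → −1. Using
theoretical rather than empirically calibrated anchors keeps scoring
deterministic and data-independent: two deployments with the same
parameter table produce identical scores. The negative window is
intentionally about half the length of the positive one; a cohort whose
intermediate sums are uniform around zero therefore shows roughly twice
the histogram mass in the bin just left of zero as in the bin just right
of it (the exact ratio under symmetric extremes is 9·S/99 ÷ S/20 ≈ 1.82
because of the −1 offset; the tests assert the ≈2× signature with that
tolerance). Values are clipped at the theoretical bounds to absorb
floating-point overshoot of order 1e-13.

**Levels.** Scores are reported to one decimal; level assignment first
rounds half-away-from-zero to an integer so the printed closed bins
(…, at-risk [−50, −1], enduring [0, 50], …) are honored exactly, e.g.
−50.4 → at-risk, −50.6 → clinical, −50.5 → clinical.

**Subscores.** Each subcategory score is the weighted average
`Σ aᵢvᵢ / Σ aᵢ` of its items' *weighted* values with `aᵢ ∈ {1.0, 0.5}`
(core/secondary). Feeding the weighted rather than raw rescaled values
into subscores propagates item-severity differentials consistently with
the overall score. Normalization mirrors the overall map at half scale:
positive averages onto [0, 100], negative onto [−1, −50], anchored at the
subcategory's own attainable extremes.

## The default parameter table

The production instrument's per-item N and weights are proprietary. The
shipped table (`data/default_bank.yaml`) is a principled reconstruction
following the published rules: severity tiering assigns N = 2 and w = 3.0
to the four gravest items (suicidal thoughts or intentions, aggression
toward others, hallucinations, sense of being detached from reality),
N = 3–4 and w = 2.0/1.5 to high-consequence items (traumatic flashbacks,
addictions, sadness/distress/hopelessness, disturbed sleep, depleted
energy, …), and N = 5–6 and w = 1.0 to items common within healthy
populations (guilt and blame, adaptability to change, …); γ = 1.5
throughout. The item→subcategory map honors the two published dual-coding
examples (*stability and calmness*: mood & outlook 1.0 + mind-body 0.5;
*unwanted, strange, or obsessive thoughts*: core cognition 1.0 + mood &
outlook 0.5), keeps every subcategory between 10 and 24 items (actual
sizes 14/10/14/10/11/11), and uses at most two assignments per item —
no description forces a third. Each entry carries a one-line rationale in
the config. All of this is data, not code: any study can ship its own
table.

The DSM-5 map (`data/default_dsm5.yaml`) encodes, per disorder, a list of
criterion symptoms each backed by ≥1 items, a minimum symptom count, and
mandatory any-of sets (e.g. depression requires ≥5 symptoms including
depressed mood or diminished interest). Symptom totals are interpreted as
*criterion* counts and match the published worked output (depression 14,
anxiety 11, bipolar 15, PTSD 20, OCD 6, schizophrenia 7, eating disorder
3, addiction 4, ADHD 8, ASD 9); the two published item→criterion examples
are honored verbatim. One item may serve several disorders; counts are
per-disorder, not deduplicated. Both percentages round half-up to integer
percent (6/11 → 55, 4/6 → 67); when a respondent has no severe symptoms
at all, the individual-share percentage is defined as 0. Frequency and
duration qualifiers of the DSM-5 are excluded — a single-sitting
questionnaire cannot capture them.

## QC pipeline

Rules run in a fixed order — duplicate source, completion < 7 min,
completion > 60 min, ease-of-understanding = no, meal gap > 16 h,
sleep > 16 h — and each excluded record is attributed to the first rule it
fails, so the ledger's counts sum exactly to the exclusion total. All
thresholds keep the boundary value (exactly 7 minutes or 16 hours
survive); the meal/sleep rules exclude strictly above 16 h, following the
tabulated wording ("over 16 hours") where the running text ("16+") is
ambiguous. Only an opaque source identifier is stored, never a network
address. The kept set is invariant under rule reordering (every rule is
record-local except duplicates, which resolve by timestamp); only the
attribution depends on order. Records with missing or unparseable
metadata are excluded under the ledger-visible id `invalid_metadata`.

## The synthetic-cohort generator

No respondent data for this instrument are publicly deposited, so the
generator is the package's test bed. Each respondent draws a latent
well-being factor z from one of three groups — healthy (default 84.45%,
z ~ N(1.10, 0.55)), at-risk (13.09%, N(−0.25, 0.25)), clinical (2.46%,
N(−1.30, 0.40)) — with the group fractions, gender mix
(61.1/36.6/1.1/1.2%) and age mix taken from the published validation
sample where printed (the three unprinted middle age brackets are
interpolated to sum to one). Ratings arise by monotone ordinal
discretization: per item, `u = z (+ shifts) + ε` with ε ~ N(0, 0.5), and
`rating = clip(round(N ± 2.5·u), 1, 9)` oriented by item format and
centered at the item's own threshold so that `u < 0` lands on the severe
side. Demographic structure enters as a −0.35 z-shift on mood- and
mind-body-linked items for the designated gender group (producing a
negative-score gap of a few percentage points, the published pattern) and
a +0.12 z-shift per age bracket above the center (negative-score share
falling from the mid-20s% in the youngest to under 15% in the oldest
bracket). Clinical respondents additionally concentrate severity on one
disorder sampled from configurable weights (default skewed toward
depression and anxiety) by shifting the mapped items' latent values by
−1.2, which is what makes end-to-end diagnostic-concordance tests
meaningful. QC violations are injected at the tabulated study rates
(2.85% duplicates, 6.27% too fast, …) by overwriting metadata fields.

What the generator does *not* emulate: item-specific loadings and
residual correlations beyond the single factor, response styles
(acquiescence, central tendency), item-level missingness, and any
real-world relationship between demographics and specific disorders.
Passing recovery tests therefore show that the *pipeline* preserves
injected structure, not that the instrument is valid on real populations.

**Rank correlation under ties.** With zero rating noise the map z → MHQ
is deterministic and monotone but step-wise constant, so nearby z values
collide onto identical rating vectors; tie-penalizing statistics
(Spearman, Kendall τ-b) then sit strictly below 1 even though the map is
perfectly monotone. `recover_structure` therefore reports Goodman–Kruskal
gamma — (C − D)/(C + D) over concordant/discordant pairs, the standard
rank statistic that ignores ties — as its rank correlation (exactly 1.0
in the noiseless limit), alongside Spearman's rho for reference. Gamma is
computed over all pairs (O(n²)), fine for cohorts up to a few thousand.

## Problem sizes and determinism

All stochastic components take explicit integer seeds
(`numpy.random.default_rng`); a fixed seed reproduces cohorts
byte-identically. The test suite exercises the scoring algebra
exhaustively where feasible (all 729 rating vectors of a reduced 3-item
bank against an independent brute-force evaluation; all 423 rating×item
severity pairs), uses 1,000–10,000 random vectors for monotonicity and
bounds properties, and validates effect-sign recovery over 100 seeded
replicates of n = 2000 cohorts — sizes at which every result is stable
while the whole suite runs in well under a minute of compute for the unit
tests and a few tens of seconds for the replicate study.

## Known limitations

* The default parameter table is a documented stand-in, not the
  proprietary production values; absolute scores are comparable only
  within one parameter table.
* Whether the deployed instrument's negative normalization is linear is
  not published; only its endpoints and the ≈2× compression signature
  are, and this package's piecewise-linear choice reproduces those.
* The DSM-5 mapper is a severity-only screen, not a diagnostic
  instrument.
* `allow_partial` scoring (renormalizing over answered items) is an
  off-spec convenience and disabled by default; the reference behavior is
  a hard error on missing ratings.
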