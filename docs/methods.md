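# Methods

## Disproportionality analysis

A spontaneous-report corpus is reduced to a 2×2 table per (drug,
reaction-set) pair: `a` reports of the reaction of interest naming the
index drug, `c` the drug's other reports, `b`/`d` the same split in a
comparator scope. The proportional reporting ratio is

    PRR = [a/(a+c)] / [b/(b+d)]

with `PRR = 0` when `a = 0` and `+inf` when `b = 0 < a`. Two comparator
conventions exist in practice. The classical one excludes the index
drug's reports from the comparator (`EXCLUSIVE_BACKGROUND`); the other
compares against the whole corpus, index reports included
(`ALL_REPORTS_BACKGROUND`). The package defaults to the all-reports
background because the worked example it reproduces — 4/1,460 index
reports versus 373/1,697,582 total, PRR ≈ 12.47 — and the dexamethasone
positive control (20/N vs the same totals, PRR 12.2) are only consistent
with that convention. The exclusive variant (here: b = 369,
d = 1,695,753, PRR ≈ 12.59) stays available by flag, as does an optional
restriction of the comparator to serious reports.

A report counts as exposed when it names the drug in *any* role —
primary suspect, secondary suspect or concomitant. The reproduced
glyburide cases were concomitant-only and were still counted, so role
filtering would change the headline numbers.

The association χ² is the Pearson statistic of the 2×2 table with the
Yates continuity correction by default (the screening cells are sparse;
χ² ≥ 4 corresponds to p < 0.05 at 1 df), computed via
`scipy.stats.chi2_contingency`; the uncorrected statistic is a flag
away. The signal rule is applied literally: signal ⇔ PRR ≥ 2 AND ≥ 3
reaction reports AND χ² ≥ 4, with PRR exactly 1 never a signal.

Two documented discrepancies in the source material: the published
glyburide table prints "Chi Q = 0.3", which no standard Pearson/Yates
recipe reproduces from the printed counts (both give ≥ 31 here); and the
glyburide association is described as significant although it fails the
χ² ≥ 4 criterion as stated. The package reports the literal rule outcome
and the standard χ²; the printed 0.3 is not a target.

### Report store

Reports live in a three-table relational layout modelled on the legacy
AERS quarterly dump: `DEMO` (one row per report: id, receive date,
seriousness, outcome codes, rechallenge/dechallenge codes, narrative),
`DRUG` (drug name + role PS/SS/C) and `REAC` (coded reaction terms),
`$`-delimited with a shared `ISR` id column; a flat CSV dialect with
`;`-joined list cells is equivalent. Drug names are canonicalized
through a synonym map shipping with glyburide → glibenclamide (one
molecule, two names). Reaction matching is case-insensitive *exact* term
equality — reactions are coded dictionary terms, not free text — with a
substring mode behind a flag. The default atrophy query is the five-term
list: muscle atrophy, muscular atrophy, musculoskeletal atrophy,
peroneal atrophy, progressive muscular atrophy.

Duplicate removal in the source analysis was manual; a deterministic
stand-in is used here: two reports are duplicates when they agree on
(canonical drug-name multiset, reaction-term set, receive date), keeping
the smallest report id. The key deliberately excludes challenge codes
and narratives. This is a coarse surrogate — with a small vocabulary it
can merge genuinely distinct reports (the synthetic generator's default
drug/reaction panels are sized so that such collisions are rare), and
nothing guarantees it matches any manual review.

Positive rechallenge/dechallenge retrieval unions the structured POS
code with a case-insensitive narrative phrase search (defaults:
"recurred after rechallenge" / "reappeared on readministration" for
rechallenge; "resolved after discontinuation" / "disappeared after
withdrawal" for dechallenge).

## Concentration–response modelling

Responses are signed percent changes (reductions of protein
content/muscle weight, or of KATP current), fitted with the
four-parameter logistic

    E(D) = Emin + (Emax − Emin) / (1 + (EC50 / D)^slope)

whose algebraic form is chosen to honour the asymptote semantics: E →
Emin as D → 0, E → Emax at saturation, E(EC50) = midpoint. No
absolute-value transform is applied; both asymptotes are typically
negative.

Fitting is nonlinear least squares (`scipy.optimize.curve_fit`, trust
region reflective) parameterised in log10-dose with log10(EC50) as the
free midpoint parameter. Several published curves have Hill slopes near
0.3, for which single-start fits in linear dose are fragile, so the
data-driven start (Emin from the lowest-dose mean, Emax from the
highest, EC50 at the geometric mid-dose, slope 1) is supplemented by a
5×5 grid over (log-EC50 across the dose span × slope in 0.25–4); the
lowest-RSS optimum wins. Standard errors come from the curvature at the
optimum, with SE(EC50) = ln 10 · EC50 · SE(log10 EC50) by the delta
method. Bounds: slope ∈ [10⁻³, 50], log-EC50 within the dose span ± 3
decades. A curve that fails every start returns `converged=False`
rather than raising; a flat curve (Emax ≈ Emin) converges but is
flagged ill-conditioned, since its EC50 is unidentifiable. At least 4
distinct concentrations are required. Published parameter rows printed
without a convergent fit are represented as `converged=False`, never
imputed.

ANOVA: the one-way decomposition (F = MS_treatment/MS_residual, p from
the F distribution at (k−1, N−k) df) is coded directly because the
result type exposes the mean squares; it is cross-checked against
`scipy.stats.f_oneway` in the tests to 1e-10. The two-way analysis
(drug × incubation time) fits an additive OLS model via statsmodels
`anova_lm` (type II, no interaction, matching how the comparison across
incubation times is used) and reports a main-effect F per factor.

**Efficacy ranking.** Drugs are ordered by potency (ascending EC50; or
by |Emax| for the efficacy variant), and each adjacent pair is joined by
`>` when the compared parameter differs significantly and `≥`
otherwise. The original post-hoc procedure behind the published symbols
is not stated; the stand-in here is a two-sided z-test on the parameter
difference using the fitted standard errors at α = 0.05. On the FDB
protein-content fits this reproduces the published string exactly
(repa.≥glib.>glimep.>tolb.>nate.); on SOL the ordering matches but one
symbol differs from print, which is expected from an unstated multiple-
comparison recipe and is why only the FDB string is asserted
symbol-for-symbol. Unfittable drugs rank last; missing standard errors
degrade the relation to `≥` with a warning.

**Viability.** A fiber is dead iff it shows a marked (>40%) change in
length or diameter *and* fails the ATP/KCl contractility challenge — the
conjunction is load-bearing, a shrunken fiber that still twitches is
alive. Mortality = dead/total × 100. Percent change versus the
contralateral control is 100 × (treated − control)/control.

## Dose translation

Body-surface-area scaling uses the standard FDA Km factors (human 70 kg,
Km 37; mouse 30 g, Km 3), which are the conventional values where none
are printed: target mg/kg = (dose/weight_source) × (Km_source/Km_target).
A ≤10 mg human dose maps to ≈1.76 mg/kg in mouse; the source text quotes
1 mg/kg from unstated intermediate assumptions, and the package reports
the Km-ratio arithmetic without forcing agreement. The circulating
concentration assumes the whole dose is confined to the blood volume
(mouse default 2.6 mL): 0.03 mg glibenclamide (494 g/mol) gives 23.4 µM,
the ≈23 µM figure that anchored the tested concentration range. The
result object carries an explicit caveat that this is an upper bound —
for a lipophilic drug the volume of distribution far exceeds blood
volume.

## Synthetic data

`gen_reports` emulates the screened corpus: each report draws exposures
independently from a 40-drug panel, then reaction terms independently
per term at their background rates, with a planted (drug, term) pair
multiplying that term's rate by a relative reporting rate ρ for exposed
reports — so the downstream PRR estimates ρ (under the all-reports
background it is slightly diluted toward ρ/(1 + f(ρ−1)) for exposure
fraction f). The muscle-atrophy background defaults to 2.2×10⁻⁴,
matching the 0.022% corpus-wide proportion. Reports are resampled until
they carry ≥1 reaction and ≥1 drug; receive dates are uniform over an
8-month window; a configurable fraction are exact duplicate copies with
fresh ids, and a fraction carry the POS rechallenge code. Every store
comes with a ledger of the planted duplicates and rechallenge ids. The
default drug and reaction panels are deliberately wide: real corpora
draw from thousands of drugs and coded terms, and a narrow vocabulary
makes distinct reports collide on the dedup key.

What the generator does *not* emulate: term–term and drug–drug
correlation, co-prescription structure, demographics, reporting-rate
time trends, near-duplicate (non-identical) reports. Passing recovery
tests therefore show that the counting statistics and the rule logic are
correct, not that the pipeline is robust to real AERS messiness.

`gen_dose_response` adds i.i.d. Gaussian noise (default σ = 3 response
%, 5 replicates — the "minimum of five sample replicates" design) to an
exact 4PL; `gen_fiber_observations` plants a death rate with dead fibers
>40% shrunken and non-contractile, plus a 10% tranche of shrunken-but-
contracting alive fibers to exercise the conjunction rule. All
generators are deterministic given (config, seed).

## Problem sizes and defaults used in the shipped analyses

Planted-signal recovery: ρ = 12 at 200,000 reports × 10 seeds (median
PRR ≈ 12.0; individual seeds swing ±40% because the expected atrophy
count among ~2,000 exposed reports is only ~5). Noisy EC50 recovery:
σ = 3, 5 replicates × 12 log-spaced doses, 50 seeds, median relative
bias ≈ −7% (well under the 15% design bound; the shallow-slope
glibenclamide/FDB row is the hardest case and is the one used). The
noise-free round trip over all 26 complete published parameter rows
recovers EC50 to ~10⁻¹⁴ relative error. The driver scripts default to a
100,000-report corpus.

## Known limitations

* The dedup key is a surrogate for manual duplicate review and can
  over- or under-merge; removal counts are only exact against the key's
  own group-by.
* The `>`/`≥` significance calls depend on the z-test stand-in; only the
  FDB protein-content string is expected to reproduce symbol-for-symbol.
* The PRR carries no multiple-testing control across drugs (none was
  applied in the source analysis) and, like all disproportionality
  statistics, measures reporting imbalance, not incidence or causation.
* The blood-volume concentration is an upper bound by construction.
* 3PL/5PL model selection, mixed-effects curve fitting and MedDRA
  hierarchy traversal are out of scope.
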