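# Methods

`patrace` implements the computational core of a stable-isotope tracing
study of propionate metabolism: how measured mass-isotopologue
distributions (MIDs) are cleaned of natural-abundance background, how a
glucose-tracer bolus yields whole-body glucose production, how
internal-standard peak-area ratios become concentrations and enzyme
activities, and how group contrasts are tested. A synthetic-cohort
generator with known ground truth makes every stage testable without any
measured data.

## Unit-resolution mass bookkeeping (`chem`)

Formulas are element→count maps. Heavy tracer atoms (`D`, `[13C]`,
`[15N]`) are distinct element symbols carrying their own mass numbers and
no natural isotopic spread; this lets derivatization arithmetic and
tracer math share one formula type, and makes the nominal m/z of a
labeled species fall out of ordinary formula addition.

Nominal masses are integer mass numbers of each element's principal
isotope (H=1, C=12, N=14, O=16, P=31, S=32, Si=28, Na=23), matching the
unit-resolution MRM transitions of a triple quadrupole, rather than
rounded exact masses. Monoisotopic masses use standard principal-isotope
exact masses; adduct m/z ignores the electron mass (≈0.5 mDa, irrelevant
at the precision used here).

Derivatizations are formula deltas: 3-nitrophenylhydrazide formation on
carboxylic acids (+C6H7N3O2 −H2O, detected as [M−H]−), acid methyl
esterification (+CH2, [M+H]+), TBDMS silylation (+C6H15Si −H), and
methoximation (+CH3N). With these, the shipped MRM registry reproduces
every internally consistent printed precursor mass (propionate 208,
acetate 194, hexanoate 250, propionyl-CoA 824, methylmalonyl-CoA 868,
methyl-carnitine 176, methyl-acetylcarnitine 218, …). Two registry
entries are deliberate exceptions: the D5-propionate transition is
registered at its printed value, which exceeds the computed
acylhydrazide mass by 3 and is reported as a failing check; and the
[2H9]carnitine entry keeps only the +9-consistent precursor (185).

Natural isotope patterns are convolutions over atoms of per-element
single-atom shift distributions, truncated with the lost tail tracked.
Abundances ship as a packaged CSV of representative terrestrial values
and may be overridden by a user CSV of identical schema. Tests verify
the convolution against an independent exhaustive multinomial-enumeration
oracle for formulas up to 24 atoms.

## Natural-abundance correction (`mid`)

The measured MID of a derivatized fragment mixes tracer labeling with
the natural heavy-isotope background of every atom in the measured ion.
The correction matrix M has column j equal to the expected measured
pattern of the species with j tracer atoms fixed heavy: the natural
pattern of the full fragment formula minus j atoms of the labeled
element, shifted by j and convolved with the tracer-purity binomial over
the j labeled positions. Atoms of the tracer element outside the labeled
positions (derivative carbons, for instance) keep their natural spread —
standard practice for GC-MS fragments. Truncation uses K = n + 4 rows.

Deconvolution solves measured ≈ M·x under x ≥ 0 by non-negative least
squares, then renormalizes; NNLS prevents the negative mol fractions an
unconstrained inverse produces on noisy data (the unconstrained solution
remains available via `method="lstsq"` for comparison). A noiseless
forward–inverse round trip recovers any MID to L∞ ≤ 1e-6; with 1%
multiplicative noise the median L∞ error stays below 0.02. Tracer purity
defaults to 0.99 when unstated.

Dual-label tracers (one 15N plus several 13C) are folded onto a single
mass-shift axis, since unit-resolution data cannot separate a 13C from a
15N shift; ladder rungs fill in tracer-list order. Per-element resolved
correction is out of scope.

Summaries: average carbon labeling Σ(mᵢ·i)/n ∈ [0,1] (linear in the MID,
equal to m₁ when n=1) and single-isotopologue enrichment read-off.

## Bolus turnover (`turnover`)

A di-deuterated glucose bolus D (µmol/kg) mixes into the body glucose
pool Q and decays as unlabeled glucose appears:

    E(t) = E0·e^(−kt),  E0 = D/(D+Q),  Q = D(1−E0)/E0,  Ra = k·Q.

This is the simplest single-pool model consistent with a bolus-decay
sampling design at quasi-steady state; a Steele-type non-steady-state
correction is deliberately not applied (limitation: Ra is interpreted as
a quasi-steady production rate over the 90-min window). The default fit
is enrichment-weighted log-linear regression (variance-stabilizing under
multiplicative noise); nonlinear least squares is available and agrees to
machine precision on noiseless data, never worse in SSE on noisy data.
Fitted k is floored at zero. Default dose 0.04 g/kg of the 182 g/mol
tracer; sampling at 5, 15, 30, 45, 60, 75, 90 min.

Monte-Carlo recovery at 5% enrichment CV gives median |ΔRa|/Ra well
under 15% (the acceptance suite measures it over 200 seeds).

## Quantification and enzyme activities (`quant`)

Isotope-dilution arithmetic: conc = (area/area_IS)·RF·amount_IS/sample.
Response factors default to 1 (co-eluting labeled IS, no calibration
curves). Tissue amounts follow the 20 mg/ml homogenization convention.
Plasma ammonia uses the 0.5 nmol 15N spike into 20 µl plasma (area ratio
1 ⇒ 25 µM). Enzyme activity is product amount divided by reaction time
and tissue mass in the reaction; shipped geometries: PCC (30 min, 10 µl
homogenate, methylmalonyl-CoA product, D9-pentanoyl-CoA IS), SDS (2 h,
100 µl), BCAT (30 min, 100 µl). Q3 product ions are registry constants
(neutral losses: 43 for the 3-NPH series, 507 for acyl-CoAs), not derived
from fragmentation chemistry.

## Statistics (`stats`)

Two-group contrasts use the pooled-variance Student t with a one-tailed
p (groups are equal-sized and small); the tail direction is an input,
and `"auto"` uses the observed direction with an explicit post-hoc flag.
Multi-group comparisons use one-way ANOVA; many-to-one post-hoc testing
uses a Dunnett adjustment computed by Monte Carlo: the joint null of the
k correlated two-sided t statistics sharing one control and one pooled
MSE is simulated (group means normal, pooled variance χ²), and the
adjusted p is P(maxᵢ|Tᵢ| ≥ |t_obs|) with a (1+count)/(1+n_mc) estimator.
It is seed-deterministic, bounded below by the raw many-to-one p and
above by the Bonferroni bound within Monte-Carlo error, and cross-checked
in tests against the quadrature implementation in scipy. Volcano tables
rank metabolites by ascending p with stable ties; no cross-metabolite
multiplicity correction is applied by default (a BH flag is a
deliberate non-default).

## Synthetic cohorts (`synth`)

The generator emulates a fed-vs-fasted design with five animals per
group. Defaults, chosen once: measurement CV 10% (multiplicative
log-normal, unit mean; additive Gaussian by flag); baseline pools and
fasted/fed multipliers in the directions the biology implies (portal
propionate ×0.25, other portal SCFAs ×0.5, ketones ×2.2,
propionylcarnitine ×0.38, methylcitrate ×0.5, hexanoate ×1.5); tracer
cascades with transfer fractions set so terminal propionylcarnitine
labeling stays below 30% (M6 valine → M5 KIV → M4 3HIB → M3 C3-carnitine;
M4 threonine → M4 2KB → M3 C3-carnitine; M3 propionate → M3 C3-carnitine
→ citrate → glucose); bolus ground truth Q = 1800 µmol/kg,
Ra = 150 µmol/kg/min (fasted-mutant multiplier 0.6), physiological for a
fasted mouse. A master seed spawns independent child streams per table,
so outputs are byte-reproducible and adding a table never perturbs the
others.

What the generator does not emulate: real chromatographic interference,
drift and batch effects, non-multiplicative detector noise, inter-animal
covariance between metabolites, or genuine flux dynamics (cascade
transfer is a static fraction, not a kinetic model). Passing recovery
tests therefore demonstrates the correctness of the estimators under the
stated noise model, not robustness to every artifact of real data.

## Numerical choices and limitations

- NNLS tie-break: all-zero solutions are rejected; near-rank-deficient
  matrices (condition number > 1e8) warn but still solve.
- Constant enrichment time courses fit k = 0 exactly; enrichments are
  validated into (0, 1) and times must be strictly increasing.
- Identical groups give t = 0, p = 0.5; zero pooled variance with equal
  means is treated as "no evidence", with unequal means as an error.
- Rank-1 volcano recovery is only a meaningful property when the largest
  configured effect is well separated: with several near-tied large
  effects at n = 5 the sampling spread of the t statistic overlaps and
  no estimator can attain near-certain top ranking. The recovery test
  uses a panel with one dominant effect; the default cohort, which has
  several simultaneously strong effects, is used for the fold-change
  recovery checks instead.
- Charge states are limited to ±1 and isotope fine structure is not
  modeled; printed high-resolution masses are matched only to ~2 mDa.
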