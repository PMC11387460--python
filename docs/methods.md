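# Methods

`faerspv` implements the standard frequentist/Bayesian signal-detection stack
used in retrospective pharmacovigilance studies of spontaneous-report
databases, together with a synthetic report generator that makes every stage
testable against known ground truth.  This note records the statistical
model, the preprocessing conventions, the generator's assumptions, and the
design decisions taken where the field's practice is not unique.

## The disproportionality model

For a target drug *D* and event *E* (a MedDRA Preferred Term, or a System
Organ Class after within-report de-duplication), the deduplicated database is
cross-classified into the 2×2 table

|              | event *E* | other events |
|--------------|-----------|--------------|
| reports with *D*    | a | b |
| reports without *D* | c | d |

Each report contributes at most one count per event: `a + b` always equals
the exposed-cohort size and `c + d` the background size.

Four statistics are computed per table:

* **ROR** — reporting odds ratio `(a·d)/(b·c)` with the Wald 95% CI
  `exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`.
* **PRR** — proportional reporting ratio `[a/(a+b)] / [c/(c+d)]`, paired with
  the Pearson χ² statistic of the table
  (`N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`).  Yates' continuity correction is off
  by default — the classical PRR companion statistic — and available via a
  flag for sensitivity analyses.
* **IC** — the BCPNN information component, a shrunken log₂
  observed-to-expected ratio.  The closed-form posterior moments (Bate et
  al., 1998 parameterisation) are used with priors α₁ = β₁ = 1, α = β = 2,
  γ₁₁ = 1 and γ chosen so the prior IC expectation is zero:

      E(IC) = log₂[(n₁₁+1)(N+2)² / ((N+γ)(n₁.+1)(n.₁+1))],   γ = (N+2)²/((n₁.+1)(n.₁+1))

  with the analogous closed-form variance; `ic_lo = E(IC) − 1.96·√V(IC)`.  A
  flag selects the `E(IC) − 2·SD` bound some reporting-database studies use
  instead.  The full MCMC BCPNN posterior and EBGM/MGPS are out of scope.

A pair is flagged as a **signal** when all four parts hold: `a ≥ 3`,
`ror_lo > 1`, `prr > 2` with `χ² > 4`, and `ic_lo > 0`.  The count floor is
inclusive (three reports suffice); the other thresholds are strict.  No
multiple-testing adjustment is applied — flagged pairs are screening
hypotheses, not confirmed associations — and this is deliberate: it mirrors
standard signal-detection practice, where the combined criterion itself is
the false-positive control.

### Numerical conventions

* **Zero cells.** When a raw row or column margin is zero the frequentist
  statistics are undefined and reported missing with a reason code.  When
  only a single cell is zero, the Haldane–Anscombe correction (+0.5 to all
  four cells) is applied to ROR/PRR/χ² and the result is flagged
  `zero_cell_corrected`.  The IC needs no correction: its priors keep it
  defined even at a = 0.
* A missing component always fails the signal rule.

## Breslow–Day comparison of two drugs

To ask whether an event is disproportionally reported to the same degree for
two drugs, their 2×2 tables are treated as strata.  The common odds ratio
under homogeneity is the Mantel–Haenszel estimate
`OR_MH = Σ(aₖdₖ/Nₖ) / Σ(bₖcₖ/Nₖ)`; per stratum the expected a-cell `ã` is the
admissible root of the quadratic `ψ = ã(r₂−c₁+ã)/((r₁−ã)(c₁−ã))` at
`ψ = OR_MH`, with variance `Var = [1/ã + 1/(r₁−ã) + 1/(c₁−ã) + 1/(r₂−c₁+ã)]⁻¹`.
The statistic `Σ(aₖ−ãₖ)²/Varₖ` is χ² with K−1 degrees of freedom under
homogeneity.  Tarone's correction — subtracting `(Σ(aₖ−ãₖ))²/ΣVarₖ` — is on
by default because the common OR is estimated, with a flag for the classic
uncorrected statistic.

Stratum construction: each drug's exposed set is compared against the shared
rest-of-database background with the *other* drug's exposed reports (and
dual-exposed reports) removed, so no report enters two strata.  The two
strata still share the same background rows; with backgrounds an order of
magnitude larger than the exposed sets, the induced correlation is
negligible, and the calibration study (independent binomial strata, 2,000
events, shared lognormal OR) confirms a type-I error within [0.03, 0.07] at
α = 0.05.

In the head-to-head comparison table the per-drug ROR columns come from each
drug's own full cohort (exposed vs all other reports) so they agree with the
per-drug signal tables; only the Breslow–Day p-value uses the disjoint
strata.  Events signalled for one drug only carry NA on the other side.

## Preprocessing conventions

* **Deduplication.** One report per case: the latest FDA receipt date wins;
  ties go to the numerically largest `primaryid`, then the largest case
  version.  The receipt date of the version row is used because it is the
  only per-version date reliably present.  Reports without a `caseid` cannot
  be merged and are kept, flagged.
* **Drug standardisation** is dictionary lookup: aliases (brands, salts)
  map to canonical ingredients; in substring mode the longest matching alias
  wins, so combination brands ("CLARITIN-D") are not swallowed by their
  parent brand.  No NLP normalisation (spelling, dose parsing) is attempted.
* **Exclusions** are report-level, case-insensitive substring patterns over
  all drug strings in a report: if any drug matches, the whole report leaves
  the exposed cohort (co-formulations confound attribution) but stays in the
  background.  Exclusion lists are pure configuration; `configs/` ships the
  published list verbatim (identical for both antihistamine cohorts, and
  naming "reactine", a cetirizine brand) plus a corrected loratadine variant
  that swaps in desloratadine, because the published criteria are internally
  inconsistent and guessing a single intent would hide the choice.
* **Role filter** defaults to suspect drugs ({PS, SS}), widenable to all
  roles, per standard disproportionality practice.
* **Units.** Ages normalise to years (YR×1, DEC×10, MON÷12, WK×7÷365.25,
  DY÷365.25, HR÷8766; unknown code → missing; results above 150 years →
  missing), weights to kg (KG, LBS×0.453592, GMS÷1000), both rounded to two
  decimals so normalisation is idempotent.

## Descriptive tables

Within every categorical block of the demographics summary the percent
denominator is the sum of the block's displayed counts.  Sex and reporter
blocks carry an explicit Unknown row, so their denominator equals the cohort
size; outcome percents are shares of outcome *occurrences* (a report may
carry several codes, each counted once); country and route percents are
shares among reports with a known value.  This is the only convention under
which the published characteristics table's percents reproduce from its own
counts (e.g. 20218/25356 = 79.74% for the United States row, where 25356 is
the sum of the listed country counts, not the cohort size of 28051), and the
reconstruction test enforces it for every row.  Quartiles use linear
interpolation between order statistics.  Top-K indication/concomitant
percents use as denominator the number of exposed reports carrying at least
one record of that kind, since a cohort-size denominator cannot reproduce
published concomitant shares; ties at rank K break alphabetically.

## The synthetic generator

Each report independently samples 1–3 drugs (by a prevalence vector, Zipf by
default) and k = 1 + Poisson(μ) reaction PTs.  A planted association
multiplies the target PT's baseline probability by λ in reports containing
the drug; the tilted distribution is renormalised per report and sampled
without replacement by Gumbel top-k perturbation, which is distributionally
identical to successive weighted draws.  Renormalisation keeps the
reactions-per-report margin stable across λ, at the cost that the marginal
reporting odds ratio is attenuated relative to λ (for λ = 10 at 1% baseline
the implied ROR is ≈ 9.8, measured by an independent sequential-draw
simulation of the same scheme); tests therefore check recovery against the
scheme's own implied value, not against λ.

On top of the clean reports the generator injects a configurable fraction of
duplicate case versions (receipt dates offset +1..+90 days so the dedup rule
has to do real work), replaces a fraction of drug names with brand aliases,
and blanks fields per a missingness table (defaults: age 20%, weight 40%,
sex 10%, country 5%, route 30% — chosen as plausible spontaneous-report
missingness levels).  Demographics are sampled once and fixed: lognormal age
(median 40 y), 52/30/18% F/M/unknown sex, consumer-dominated reporters,
US-dominated countries.  All randomness derives from one master seed through
named `SeedSequence` child streams.

What the generator does **not** emulate — and hence what passing tests do
not show about real FAERS data: real marginal reporting frequencies and drug
market shares, secular trends and event-driven reporting waves, masking and
competition bias between drugs, correlated misspellings, or free-text noise
beyond brand aliasing.  Results on synthetic data validate the machinery,
not the clinical conclusions drawn from any particular extraction.

## Validation studies and problem sizes

* Planted-signal recovery: 100 replicates of a 100,000-report database with
  one λ = 10 pair (expected exposed-with-event count far above the a ≥ 3
  floor); the pair must be flagged in ≥ 90% of replicates.
* False-positive control: one 100,000-report database with all λ = 1, 20
  drugs × 10 PTs = 200 pairs; fewer than 5% of pairs with a ≥ 3 may be
  flagged.
* Breslow–Day calibration: 2,000 simulated homogeneous-OR events, expecting
  a rejection rate within [0.03, 0.07] at α = 0.05.
* Statistic oracles: 1,000 random strictly-positive tables against
  independently coded closed forms at 1e-10 relative; Breslow–Day against
  `statsmodels`' stratified-table test.

These sizes were chosen so each study resolves its acceptance band with
comfortable Monte-Carlo margin while the whole suite stays convenient to run
on a single CPU.

## Known limitations

* PT→SOC mapping is flat (no HLT/HLGT hierarchy); MedDRA is licensed, so
  only a mock dictionary ships and real analyses must supply their own.
* The legacy (pre-2012) LAERS layout and embedded-'$' fields are unsupported;
  malformed rows are reported, not repaired.
* No EBGM/MGPS, no time-scan detection, no formal ratio-of-ROR interval.
* Signal flags are screening output; without multiple-testing control they
  must not be read as confirmed risks.
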