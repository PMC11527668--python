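# Methods

## Scope and data model

`pvsignal` analyses spontaneous adverse-event reports in the quarterly
ASCII dialect used by large regulatory reporting systems: seven
"$"-delimited tables (DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI) keyed by a
report-version identifier (`primaryid`), with a case identifier (`caseid`)
shared across successive versions of the same case.  Input is decoded as
Latin-1 (real extracts contain non-UTF-8 bytes) and written back as UTF-8;
column names from both the modern and the older ISR-era schema are accepted
through a synonym map.  Partial dates (`YYYYMM`, `YYYY`) are retained with
an explicit precision flag rather than imputed or discarded.

## Deduplication

A case accumulates report versions over time.  Analysis keeps exactly one
DEMO row per `caseid`: the one with the maximal FDA receipt date, ties
broken by the maximal `primaryid` — the standard regulatory-practice
reading of "keep the latest version".  Rows in child tables belonging to
dropped versions are removed, restoring referential integrity.  Reports
without a `caseid` cannot be grouped; they are kept as singletons and their
count is reported rather than silently resolved.  Deduplication is
idempotent and order-independent.

## Case selection

A report enters the cohort when (i) at least one DRUG row matches the drug
dictionary with a role code in the role filter (default: primary suspect
only) and (ii) at least one REAC row carries a preferred term from the
query set.  Matching is exact on a normalized form (uppercase, trimmed,
internal whitespace collapsed, punctuation stripped); an opt-in
word-boundary substring mode exists for sensitivity analyses but is off by
default because free-text drugname fields with dosage suffixes make
substring counts irreproducible.  The bundled defaults are the seven
PARP-inhibitor generics with their brand names and development codes, and a
twelve-term renal-event query set (acute kidney injury, blood creatinine
increased, blood urea abnormal, glomerular filtration rate decreased, renal
impairment, oliguria, anuria, dialysis, hemodialysis, peritoneal dialysis,
nephropathy toxic, tubulointerstitial nephritis).

Reports co-suspecting two study drugs appear once per drug in per-drug
blocks; the summary carries both the distinct-report count and the
report–drug pair count so either convention can be read off.  Ages are
normalized to years (DEC = 10 y, MON = 1/12 y, WK = 7/365.25 y, DY =
1/365.25 y, HR = 1/8766 y; a missing unit with an age present is assumed
years and logged).  Age bins are left-inclusive: <30, 30–44, 45–64, 65–74,
75–84, ≥85.  Percentages are rounded half-up to two decimals, the
convention of printed report tables; full precision is retained internally.

## Disproportionality statistics

For drug D and event set E over the deduplicated database, the 2×2 table is
a = reports with D (suspect) and E, b = E without D, c = D without E, d =
neither.  Counting is at the unique-report level by default; an
occurrence-level option counts REAC rows instead (some published tables
appear to use it — the two conventions differ whenever one report carries
several target terms).

The four measures and their signal criteria:

| measure | formula | criterion |
|---|---|---|
| ROR | (a/b)/(c/d); 95% CI = exp(ln ROR ± 1.96·s), s = √(1/a+1/b+1/c+1/d) | CI low > 1 and N ≥ 2 |
| PRR | (a/(a+c))/(b/(b+d)); χ² (see below) | PRR ≥ 2, χ² ≥ 4, N ≥ 3 |
| IC | log₂(a·N/((a+c)(a+b))); IC025 = IC·exp(−1.96·s) | IC025 > 0 |
| EBGM | a·N/((a+c)(a+b)); EBGM05 = EBGM·exp(−1.64·s) | EBGM05 > 2, N > 0 |

Two deliberate fidelity choices, both config-switchable:

* **Interval formulas are implemented verbatim.**  The IC lower bound is
  the *multiplicative* IC·exp(−1.96·s), not the canonical BCPNN posterior
  interval; it is defined only when IC > 0 (a negative IC has no meaningful
  multiplicative lower bound and is reported without one).  A
  clearly-labelled `canonical` mode provides the additive delta-method
  bound IC − 1.96·s/ln 2 instead.
* **EBGM carries no shrinkage.**  As formulated, EBGM is the unshrunk
  relative reporting ratio — identical to 2^IC — not a gamma-Poisson
  posterior mean.  It is documented and tested as such (IC = log₂ EBGM is
  asserted to machine precision), and no shrinkage fit is attempted.

The χ² accompanying PRR defaults to the four-cell Pearson statistic
(equivalently N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))); an `a_cell` variant using
only the exposed-event term (a−E_a)²/E_a is selectable, since the source
formulation is ambiguous between the two readings.

Zero cells leave the affected statistics undefined (NaN); undefined values
evaluate to "no signal".  An optional Haldane–Anscombe +0.5 correction is
available and logged.  For any table with a·d > b·c the three point
estimates obey ROR > PRR > EBGM exactly, with equality iff a·d = b·c; this
algebraic ordering is property-tested.

The scan is exposed statsmodels-style: `DisproportionalityModel(dataset,
dictionary, pt_set, ...).fit()` returns a results object holding one row
per dictionary generic with estimates, intervals, flags, `to_frame()` and
`summary()`.

## Time to onset and outcomes

TTO is the whole-day difference between the event onset date (DEMO
EVENT_DT) and the start of therapy with the matched drug (THER START_DT
linked through the matched DRUG row's sequence number).  Both dates must
have day precision; month/year-precision dates are excluded rather than
imputed, because imputation would manufacture the very medians under
study.  When several linked therapy rows qualify, the earliest start
anchors onset (the conservative choice).  Identical dates give TTO 0;
events dated before therapy start are data errors, excluded with reason
`event_precedes_start`.  Every exclusion is categorized and counted;
used + excluded = input always.

Quartiles use linear interpolation between order statistics — the
convention that yields fractional values such as 55.75.  Group contrasts
use the Mann–Whitney test (exact enumeration when both groups have n ≤ 8
and no cross-group ties, otherwise the tie-corrected normal approximation
with continuity correction), the Kruskal–Wallis test with tie correction
for more than two groups, and Pearson's χ² for rate comparisons, with the
Yates continuity correction auto-applied to 2×2 tables when any expected
frequency is below five.  scipy.stats supplies the machinery; all p-values
are two-sided.

Outcome rates (hospitalization = HO count, fatality = DE count) are
reported under two denominators — all cohort reports, and reports carrying
at least one outcome code — because published rates are frequently
ambiguous on this point; the denominator is always printed alongside the
rate, and a report with several outcome codes counts once per code.

## Synthetic SRS generator

The generator exists so every stage can be validated without access to the
real database.  Each simulated report is exposed to at most one study drug
(drug j with marginal probability p_j) and carries a target event with
probability q_j = p0·θ_j/(1−p0+p0·θ_j) when exposed, p0 otherwise — i.e.
exposure multiplies the background odds by θ_j, so the population 2×2 odds
ratio equals θ exactly under this exclusive-exposure design.  Expected
cells are available in closed form and serve as oracles for the
contingency builder.

Defaults are chosen to resemble the study conditions rather than any real
marginal distribution: background target-event probability 0.02, drug
marginals around 0.01, log-normal TTO with median 15 days and log-sd 1.3
(matching the right-skew of observed onset distributions, where the IQR
spans roughly 6–56 days around a median of 15), outcome probabilities
conditional on a target event of 0.28 (hospitalization), 0.04 (death),
0.05 (life-threatening), 0.01 (disability), 0.60 (other), 10% missing
start/event dates, 30% concomitant-drug rows, and report dates spanning
2015–2023.  Duplicate case versions are injected at a configurable rate:
a duplicated case re-appears with a fresh (larger) primaryid and a
strictly later FDA date, and the intended survivor is recorded in the
ground truth, so deduplication can be checked for exact recovery.

What the generator deliberately does not emulate: real-world reporting
bias, drug- or country-specific reporting propensities, MedDRA coding
noise, correlated missingness, or free-text drugname corruption beyond the
clean synonym.  Passing the simulation suite therefore demonstrates
correctness of the pipeline's logic under a known sampling model, not
robustness to every pathology of real spontaneous-report data.

## Simulation studies and problem sizes

The validation studies run at fixed sizes chosen to give adequate power
while keeping the default suite quick: type-I control over 200 generated
datasets of 50,000 reports with five null drugs (1,000 drug scans; the
all-four-criteria flag rate must stay under 5%); odds-ratio recovery over
200 datasets of 70,000 reports at θ = 3 with expected a ≈ 40 (median ROR
within 10% of θ, 95% CI coverage ≥ 90%); Kruskal–Wallis empirical size
over 500 simulations of four equal log-normal groups (within ±2% of the
nominal 5%); and exact survivor recovery after injecting duplicates into
1,000 cases at rate 0.2.

## Numerical choices

* Percentage and presentation rounding: decimal half-up, two decimals.
* Interval critical values: the printed constants 1.96 and 1.64 are used
  literally (not norm.ppf values); tests that compare against independent
  references combine the reference's log-scale SE with these constants.
* Date ordering for dedup uses an integer YYYYMMDD key; partial dates sort
  at the start of their period, missing dates first (so any dated version
  beats an undated one).
* Quartiles: NumPy linear interpolation (`method="linear"`).
* Degenerate inputs: all-identical samples give H = 0 / U = nm/2 with
  p = 1 and a note; zero-margin count tables are a hard error naming the
  margin; an empty cohort is a hard error for summaries.

## Known limitations

* Published signal-table rows cannot be reproduced bit-for-bit from the
  printed information alone — the b, c, d cells behind them are not
  published.  They are validated through identities and criteria logic
  instead.
* Published per-drug Ns mix counting conventions (report-level vs
  occurrence-level); both are implemented, neither is privileged.
* Some published percentage blocks imply denominators that are not stated
  (e.g. an indication block summing above its apparent denominator); the
  package always prints the denominator it used instead of guessing.
* No MedDRA hierarchy traversal: event queries are literal preferred-term
  sets.
* No multiplicity adjustment across drugs, mirroring standard
  disproportionality practice.
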