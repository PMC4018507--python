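# Methods

## Model structure and assumptions

The disease process follows the adenoma–carcinoma sequence. Clear epithelium
develops low-risk adenomas at an age-dependent annual probability (anchors at
ages 30/50/70/100: 0.021, 0.020, 0.045, 0.011); low-risk adenomas become
high-risk (0.009, 0.008, 0.008, 0.004); high-risk adenomas become preclinical
Dukes' A cancer (0.029, 0.025, 0.054, 0.115); a small direct route from clear
epithelium to preclinical A (4e-5/year) captures de novo carcinomas.
Preclinical cancer progresses A→B→C→D with annual probabilities 0.51, 0.69,
0.71 and presents symptomatically (or by chance) with stage-dependent annual
probabilities 0.04, 0.18, 0.37, 0.74. Age-dependent probabilities are
interpolated piecewise-linearly between the four anchor ages — the simplest
scheme exact at every anchor; gFOBT specificity, with anchors only at 50 and
70, is held flat outside that range. Ages are capped at 100, the last anchor.

Cycles are annual, with a cohort for every current single year of age 30–100,
each followed to age 100 or death (a deterministic expected-counts cohort
model, not a microsimulation). There is no half-cycle correction. Competing
transitions out of a state are composed on the hazard scale: each annual
probability $p_i$ becomes a hazard $h_i=-\ln(1-p_i)$, the cycle's exit
probability is $1-e^{-\sum h_i}$, split across destinations in proportion to
the hazards. This is order-independent and makes each row sum to one exactly.
One consequence worth knowing: exactly one transition can occur per cycle, so
raising one competing hazard marginally displaces the others within the same
cycle. The effect is tiny (the "null cancer mortality ⇒ identical life-years"
check holds to ~3e-8 relative, not to machine precision).

The campaign is embedded analytically rather than with a monthly engine: a
hazard increase of $(1+m)$ for $d$ of 12 months turns the annual presentation
probability $p$ into $1-(1-p)^{1+md/12}$. The multiplier applies to the whole
campaign-year hazard (prevalent and incident preclinical cases alike), in
cycle 1 only, equally at all ages, and — in the base case — equally in all
four stages; a stage-restricted variant limits it to C and D. For small $p$
the year-one excess incidence is $\approx m d/12$; for late stages
(presentation 0.74/yr) the relative excess saturates at
$r(1-p)/p \cdot m d /12$, about half that — an exact property of hazard
scaling, not an approximation error.

### Prevalent disease at baseline

The current population is not disease-free: cycle-1 campaign effects act on
prevalent preclinical cancer. Each starting cohort is seeded from a burn-in:
one cohort is run from age 30 under no-campaign dynamics (screening included)
and its alive-state distribution at each age, renormalised, initialises the
cohort currently at that age. The same burn-in fixes each cohort's split into
screening never- and ever-attenders and its in-surveillance share.

### Screening and surveillance

Biennial gFOBT invitations at ages 60–69 (configurable to 60–74; the
programme era modelled predates later extensions). Never-attenders (37%)
never test; ever-attenders test with conditional uptake 0.857 per round.
Positives (true: sensitivity 0.01/0.12/0.24 for low-risk/high-risk/CRC;
false: 1 − specificity, specificity 0.99 at 50 to 0.97 at 70) receive
colonoscopy with compliance 0.79; colonoscopy finds lesions with sensitivity
0.77/0.98/0.98 and never false-alarms. Found adenomas are removed
(polypectomy; the person returns to clear epithelium); high-risk carriers
enter surveillance, modelled as an annual colonoscopy probability of
compliance/interval = 0.83/3 — a continuous approximation of a 3-yearly
schedule that avoids tracking time-since-entry. Found preclinical cancer
becomes screen-detected clinical cancer of the same stage. Perforations
(0.3% of polypectomies, 5.2% fatal) and bleeding admissions (0.3% of
colonoscopies) are carried as expected counts and costs only; they do not
remove mass from the state engine, mirroring their scenario-analysis role.

### Survival after diagnosis

Clinical cancer carries a stage-dependent annual CRC-death probability. The
shipped fixture (`src/crcaware/data/survival_default.csv`, a synthetic table,
not a registry transcription) specifies year-since-diagnosis bands; because
the 14-state space has no post-diagnosis clock, the engine uses the constant
annual probability matching each stage's 5-year survival (~94/81/48/10% for
A–D → 0.013/0.040/0.113/0.373 per year). A `null` preset with zero cancer
mortality supports degenerate checks.

## Economics

Discounting at 3.5%/year, cycle 1 undiscounted. Utilities: 0.80 for every
alive undiagnosed state (including preclinical cancer — utility loss comes
with diagnosis), 0.70 for life after diagnosis, with no duration structure.
Treatment cost is charged once at diagnosis, linear in age at diagnosis
within the per-stage range (A £1,320–£8,375; B £1,479–£8,362; C
£1,493–£13,862; D £772–£11,198), maximum at the youngest age by default
(more aggressive treatment when young; a config switch reverses the
mapping). Screening costs: £3.36/£11.94 per completed normal/positive gFOBT,
£2.03 per non-complying invitee, £563 per colonoscopy inflated by the 7%
repeat rate, £26 pathology per lesion or cancer found, plus expected
adverse-event costs (£5,089 per perforation, £278 per bleed). The printed
per-screen kit costs are read as all-inclusive, so the mean-kits-completed
parameter (1.08) is descriptive. Campaign delivery (£0.14/person) and
incremental attendance costs (0.5 × (0.0014 × £36 + 1.52606e-5 × £200) ≈
£0.0267/person) are year-0 outlays; the share of campaign-induced visits
that are genuinely additional (50% base case, 90% scenario) scales the
latter. The per-person cost denominator defaults to the modelled 30+
population and is config-exposed, since published per-person figures imply a
slightly different denominator than the attendance totals.

## Synthetic fixtures: what they emulate and what they do not

The demography fixture is an England-like pyramid (flat to age 60, Gaussian
taper above) normalised to 33 million people aged 30+, with Gompertz
all-cause mortality (annual death probability ~5e-4 at 30 rising to ~0.32 at
100). The survival fixture is described above. The pilot-series generator
produces seeded Poisson monthly counts with an optional one-month
multiplicative step, emulating a two-region registry extract around a
campaign. None of these are fitted to ONS, registry, or life-table data.
Consequently the model reproduces the *structure* of the published analysis —
stage shift toward earlier diagnosis, monotone dose–response in campaign
magnitude and duration, near-linearity in magnitude, accounting identities —
while absolute magnitudes (deaths prevented, QALYs, ICER) are
fixture-dependent and differ from the published point estimates. Passing
tests therefore certify the mechanics and the directional science, not
calibration to English registry data.

A known consequence of the structure: confining the campaign to Dukes' C and
D yields a *negative* QALY gain on the default fixtures. Preclinical cancer
carries no excess mortality in this state space, so pulling stage-D
presentations earlier starts the high clinical-D death hazard sooner
(hazard-scaling advances diagnosis by ~1/r years, not by the campaign's one
month) and converts undiagnosed person-years at utility 0.80 into diagnosed
ones at 0.70, while only the C-stage shift (fewer progressions to D) adds
benefit. With this survival fixture the harm outweighs the benefit; the
stage-restricted scenario remains strictly worse than the all-stage one at a
matched incidence increase, which is the robust comparison. The
all-stage grid is monotone in both axes; the restricted grid is monotone in
deaths prevented but its QALY gain *decreases* with magnitude.

## Sensitivity analyses

The deterministic grid crosses durations {1, 3, 6} months with magnitudes
{5, 10, 20}%; because the campaign enters through the product
$m\times d$, cells with equal products coincide exactly. The
stage-restricted "matched incidence" scenario uses the uniform C+D
multiplier $m/\mathrm{share}(C{+}D)$ with the published symptomatic stage
shares (11/25/36/29%, which sum to 101% as printed; the divisor uses the raw
C+D share 0.65, giving 15.4%).

The PSA samples probabilities and utilities from Beta and costs from Gamma
distributions, each with standard error 10% of the mean (the source report
for the original distributions is not reproduced here; both family and
dispersion are config-overridable). Draws preserve parameter invariants by
construction: stage-ordered presentation probabilities are sorted, per-round
uptake is derived as conditional uptake × ever-participation, and the CRC
utility is capped below the cancer-free utility. Zero dispersion returns the
point estimates exactly, so a degenerate PSA reproduces the deterministic
run bit for bit. 1,000 draws (two engine runs each) take on the order of two
minutes.

The uptake-equivalence analysis bisects on the fraction of never-attenders
moved into the ever-attender group (no campaign) until the QALY gain over
the unmodified no-campaign run matches a target, reporting both the relative
reduction and the percentage-point change — the published narrative mixes
the two conventions, so both are given.

## Pilot statistics

The step-change test treats the candidate month as a single new observation
against $n$ baseline months: $t=(x-\bar b)/(s_b\sqrt{1+1/n})$ with $n-1$
degrees of freedom, two-sided. The $\sqrt{1+1/n}$ prediction-variance
inflation is the defensible default for judging one month against a
baseline; the plain $z$-style variant is an option. Degenerate baselines
(zero variance) and baselines shorter than three months are rejected.
Type-I error at $\alpha=0.01$ is verified by simulation (10,000 null Poisson
series) to lie in [0.005, 0.02]. Descriptive excesses — year-on-year change
and excess over mean + 2 sd — accompany the test, as in campaign-evaluation
practice. Seasonal adjustment is out of scope (monthly variation is a known
caveat of such series, not modelled here).

## Numerical choices and limitations

- Row sums of every transition matrix are exact to ~1e-15 by construction;
  mass conservation per cohort holds to 1e-9 relative over the full horizon.
- The engine equals explicit dense matrix products to 1e-12 on small
  instances (the cohort-advancement path has no approximation beyond the
  state space itself).
- Bisection tolerance for uptake equivalence is 0.5 QALYs over a ~33M
  population; 40 iterations bound the search.
- Problem sizes: 71 cohorts × ≤70 annual cycles per run; 1,000 PSA draws;
  10,000 null series for test calibration. A full acceptance run completes
  in about two minutes on one core.
- Not modelled (out of scope by design): emergency presentation as a
  diagnosis route, other lower-GI conditions detected by the campaign,
  flexible-sigmoidoscopy screening, tumour-location effects (the proximal
  fraction 0.38 is carried descriptively), calibration re-estimation, and
  phase-of-care cost structures.
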