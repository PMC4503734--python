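# Methods

`babblercalls` re-implements, as a tested pipeline over synthetic data, a
spatial analysis of where subordinate members of territorial, cooperatively
breeding bird groups (modelled on Southern pied babblers, *Turdoides
bicolor*) place their self-advertisement loud-calls, and whether that
placement targets an audience of potential breeding partners in
neighbouring groups.

## Territory estimation (a-LoCoH)

A group's utilisation distribution is estimated from its GPS fixes with the
adaptive "sphere-of-influence" local convex hull method. For every fix
(the *root*), the other fixes are sorted by ascending distance to the root
and added while the **cumulative** distance stays within a budget `a`
(metres); the convex hull of the root plus this neighbour set is one local
hull. Hulls are sorted ascending by area (ties: larger member sets first,
then root index — a deterministic "densest-first" order) and unioned until
the union covers at least `ceil(q * n)` of the `n` fixes; that union is the
density isopleth at level `q`. Default levels are 0.50, 0.75 and 0.95, and
the 95% isopleth is taken as the territory.

Choices that the method itself leaves open:

* **`a` value.** Default is the maximum pairwise distance among the fixes,
  the standard starting heuristic for the adaptive variant. It is
  user-overridable and recorded in every `Territory` for provenance.
* **Boundary points** count as covered (closed polygons): an isopleth
  "encompassing" a fraction of fixes is read inclusively.
* **Duplicate fixes** are retained and each counts towards coverage; they
  encode utilisation intensity. A fix set whose hulls are all degenerate
  (all fixes identical) raises an error rather than returning a zero-area
  territory.
* **Coverage threshold** uses the ceiling of `q * n` ("at least" semantics;
  matters at small `n`). Because isopleths are unions of growing prefixes
  of the same sorted hull list, nesting of levels holds by construction.

Coordinates must be planar metres in any projected system; at a study-site
extent of a few kilometres and handheld-GPS accuracy (<10 m), the choice of
metric projection is immaterial, so the package deliberately performs no
geodesy.

## Where calls fall: territory bands

Each eligible caller's calls are classified into the innermost isopleth
band containing them: inside the 50% isopleth (`core50`), between 50 and
75% (`band50_75`), between 75 and 95% (`band75_95`), or outside
(`outside95`). If calling simply followed group movement, the three inner
bands would hold 50%, 25% and 20% of calls. These expectations are
**deliberately not renormalised** (they sum to 0.95): the goodness-of-fit
compares the three inner bands only (df = 2) and the `outside95` count is
reported separately. Analyses are run twice throughout — on raw call counts
and on deduplicated *calling locations* (coordinates snapped to a 1 m grid,
well inside GPS accuracy) — because repeated calls from one perch are not
independent.

Callers qualify with at least ten located calls in a season (inclusive).

## Border targeting

For every pair of groups, the *inclusion area* is the intersection of the
focal 95% isopleth with the 100 m buffer (Minkowski dilation, round joins,
64 quadrant segments ≈ 1e-4 relative area error) of the neighbour's 95%
isopleth. Clipping to the focal territory makes the area-proportional
expectation coherent: if calling were spread evenly over the focal
territory, the expected number of calls within 100 m of a neighbour is
`total_calls / focal_area_ha * inclusion_area_ha`.

A neighbouring group counts as a **neighbour** only when the inclusion area
is at least `min_border_ha` (default 1 ha). Sliver contacts — territories
that come within 100 m over a few hundred square metres — otherwise produce
per-hectare rates of essentially unbounded variance (one stray call in
0.02 ha is a rate of 50/ha), which would dominate every paired comparison.
A call lying inside two neighbours' buffers counts towards both borders,
and the report logs the number of such multi-assigned calls.

Relatedness is the additive pedigree relationship computed by the tabular
method (processing individuals parents-first): `A(i,i) = 1 + A(dam,sire)/2`
and `A(i,j) = (A(j,dam_i) + A(j,sire_i))/2`; unknown parents are founders.
A neighbouring group is *related* when at least one of its dominants has
r ≥ 0.25 to the caller (threshold inclusive); a *potential breeding
partner* is an unrelated (r < 0.25), opposite-sex adult (≥ 365 days
post-hatch, inclusive) neighbour-group member. Unknown-sex individuals
count as adults but are excluded from partner and same-sex tallies.

Four paired comparisons of per-hectare call and location rates are
assembled per caller: related vs unrelated borders (rates pooled within
each category when a caller has several — summed calls over summed area —
since choosing one would be arbitrary); the neighbour with the most vs
fewest adults; most vs fewest potential partners; and a same-sex control
(most vs fewest unrelated same-sex adults). Ties in a selection metric are
broken by lexicographic group id and logged. Callers lacking the required
neighbours for a table are excluded from that table and logged.

Statistics follow the field conventions exactly: Pearson goodness-of-fit
with df = k − 1 over the k compared categories and no continuity
correction (three bands → df = 2; related/unrelated pooled counts against
their area-proportional expectations → df = 1), and two-sided paired t
tests with sample standard deviation and df = n − 1. Zero-variance,
zero-mean differences give t = 0, p = 1; zero variance around a non-zero
mean is an error.

## Cost of calling

Each individual's heavy-calling session (≥ 6 advertisement bouts) is
paired with the nearest-in-date zero-bout session within 14 days (smallest
gap wins; earliest calling date on ties; one pair per individual), and the
daily mass changes (end minus start of session, grams) are compared with a
paired t test.

## The synthetic population

No field data accompany the analysis, so a generator produces complete
datasets with the structure the pipeline assumes. Its defaults are the
study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| groups | 6 | callers came from six social groups |
| fixes per group-season | 300 | stated sampling effort |
| group size | 2–15 (size-2 groups bumped to 3 so a caller exists) | stated range |
| calls per caller | 26 | mean located calls per caller (~26) |
| movement | AR(1), θ = 0.1, σ = 180 m | stationary sd ≈ 413 m → 95% isopleths ≈ 150–250 ha, making 100 m ≈ 5–7% of territory diameter |
| grid spacing | 1600 m (5% jitter) | neighbouring 95% isopleths abut |
| border bias π | 0.5 | planted edge preference at the recovery-experiment level |
| partner exponent γ | 2 | border choice ∝ (1 + partners)^γ among unrelated borders; (1+count) avoids zero-probability borders |
| related-neighbour probability | 0.5 | roughly half of borders related, as in the field sample (8 vs 9) |
| weights | baseline +2 g, calling effect 0 g, noise 1 g | no mass cost observed in the field; 75–95 g birds |

Movement is a mean-reverting (AR(1)) walk rather than a mechanistic
foraging model — the simplest process giving a dense central utilisation
with realistic nested isopleths. Group composition puts one dominant pair
per group; subordinates are pedigree offspring of their dominants; with
the configured probability, one dominant of a neighbouring group is made a
full sibling of the focal caller (a disperser from the caller's natal
group), which also makes that neighbour's subordinates r = 0.25 niblings.
Calls are placed at a uniformly chosen movement fix, except that with
probability π a call is placed uniformly inside one unrelated-border
inclusion area chosen with probability ∝ (1 + n_partners)^γ. A single seed
drives everything; the same seed reproduces the dataset byte-for-byte.

What the generator does **not** emulate — and hence what passing tests do
not show about field data: temporal autocorrelation structure beyond AR(1),
observation-session clustering of calls (non-independence the source
analysis also could not model), seasonal drift in body mass, demographic
turnover, sex-biased dispersal, and GPS measurement error (coordinates are
exact; the 1 m location rounding therefore only merges genuinely repeated
placements).

## Recovery experiments

The type-I/power experiments (`babblercalls.experiments`) hold a small set
of independent landscapes fixed (fixes, territories, compositions) and
resample call placement per replicate, since call placement is the
randomness the tests address; this keeps 1000-replicate experiments at
desk scale (a 4×3-group landscape trimmed to 10 callers × 25 calls each).
Two calibration facts are worth recording. First, the three-band statistic
referred to chi-squared(2) is approximate by construction: the 5%
outside-band is dropped (the statistic's null mean is 2.05, not 2) and
isopleth coverage overshoots `ceil(q n)` by a few fixes at n = 300, so the
no-bias rejection rate sits near, not at, 0.05 (observed ≈ 0.05–0.07).
Second, the weighing design's paired difference is
`effect + (e1 − e2)`, sd √2·noise, so its power has the closed noncentral-t
form the Monte-Carlo run is checked against.

## Numerical choices

Geometry uses shapely (GEOS) throughout: `covers` for boundary-inclusive
point-in-polygon, `unary_union` for isopleths, `buffer(quad_segs=64)` for
dilations. Chi-squared and t tail probabilities come from scipy
(`chi2.sf`, i.e. the regularised upper incomplete gamma, and `t.sf`); the
test suite checks them against sympy's arbitrary-precision incomplete
gamma/beta to 1e-10. Dataset CSVs are written with 17-significant-digit
floats and parsed with correctly-rounded conversion so a write/read
round-trip is bit-exact. All tie-breaks (hull ordering, neighbour
selection, weight-day pairing) are specified and deterministic.

## Known limitations

* Per-caller calls are treated as independent; session-level
  non-independence is not modelled (flagged, not fixed, by the source
  analysis too).
* The related/unrelated df = 1 test pools counts over callers; a per-caller
  mixed model is out of scope.
* Relatedness is pedigree-derived only (no marker-based estimates); the
  tabular recursion handles inbred pedigrees but no inbreeding adjustment
  beyond it is attempted.
* Only the adaptive (`a`) LoCoH variant is implemented; `k`- and
  `r`-variants, kernel home ranges and fix thinning are out of scope.
* Areas are planar; no geodesic computation.
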