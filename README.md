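# babblercalls

Spatial analysis of **where subordinate birds in territorial family groups
place their vocal advertisements**, built for behavioural ecologists
working with GPS-located call data from cooperatively breeding species
such as the Southern pied babbler (*Turdoides bicolor*).

In these societies a dominant pair monopolises breeding, so subordinates
must advertise to neighbouring groups. The package asks, for each focal
caller:

1. **Do calls follow group movement?** Territories are estimated from
   group GPS fixes with the adaptive local convex hull method (a-LoCoH):
   local hulls around every fix (nearest neighbours whose cumulative
   distance fits a budget *a*) are unioned densest-first into the smallest
   areas covering 50%, 75% and 95% of fixes. If calling tracked movement,
   the three inner bands would hold 50% / 25% / 20% of calls; the pooled
   counts are tested with a Pearson goodness-of-fit (df = 2).
2. **Are borders with particular neighbours targeted?** The *inclusion
   area* of a neighbour is the focal 95% isopleth clipped to a 100 m buffer
   around the neighbour's 95% isopleth. Under even calling, the expected
   calls there are `total_calls / focal_area_ha × inclusion_area_ha`;
   observed counts on related vs unrelated borders (a neighbour is related
   when a dominant has pedigree relatedness r ≥ 0.25 to the caller) are
   tested with df = 1, plus paired per-hectare comparisons: related vs
   unrelated, largest vs smallest group, most vs fewest *potential
   breeding partners* (unrelated opposite-sex adults), and a same-sex
   control.
3. **Does calling cost body mass?** Daily mass change on heavy-calling
   days (≥ 6 bouts) is paired with the nearest quiet day within two weeks
   (paired t test).

Because no field dataset is distributed, a first-class synthetic generator
(`babblercalls.synthetic`) produces complete study populations — cohesive
AR(1) group movement, 2–15-member groups with one dominant pair, pedigree
kin links to neighbouring dominants, and callers with a configurable
border/partner preference — with recoverable planted effects. See
`docs/methods.md` for the model and all defaults.

## Worked example

```sh
python analysis/01_simulate_population.py --seed 1   # writes results/data/
python analysis/02_estimate_territories.py
python analysis/03_band_occupancy.py
python analysis/04_border_targeting.py
python analysis/05_calling_costs.py
```

Step 03 prints, for the default population (six groups, one caller each,
26 calls per caller, planted border bias 0.5):

```
pooled band occupancy (all eligible callers):
     unit      band  observed  expected
    calls band50_75        46      39.0
    calls band75_95        58      31.2
    calls    core50        50      78.0
    calls outside95         2       0.0

calls:     X^2 = 34.328, df = 2, P = 3.513e-08
locations: X^2 = 41.832, df = 2, P = 8.245e-10
```

Reading: were calling to follow group movement, 78 of the 156 calls would
fall in the territory core; instead the 75–95% band holds nearly twice its
expected share — the planted edge preference, recovered with the same test
shape (three bands, df = 2) the field analysis uses. Step 04 then shows the
preference is structured: calls concentrate on *unrelated* borders
(df = 1 test) and the paired comparison is significant only for the
most-vs-fewest potential-partner contrast (`t = 3.107, df = 4, P = 0.036`),
not for group size or the same-sex control. Step 05 finds no mass cost of
calling (`t = -0.318, df = 7, P = 0.76`), consistent with in-territory
advertisement being cheap relative to prospecting.

The same pipeline runs from the shell on any dataset in the five-file CSV
format (fixes, calls, individuals, pedigree, weights):

```sh
babblercalls simulate --seed 1 --out data/
babblercalls territory --fixes data/fixes.csv --group G01 --out g01.geojson
babblercalls run-all --dataset data/ --out run/
```

## Layout

- `src/babblercalls/` — library: `core_io` (types + CSV/GeoJSON I/O),
  `locoh` (a-LoCoH isopleths), `pedigree` (relatedness, neighbour
  profiles), `audience` (bands, buffers, border stats, paired tables,
  weight pairing), `stats` (chi-squared, paired t), `synthetic`
  (generator), `experiments` (recovery experiments), `pipeline` + `cli`.
- `analysis/` — the numbered drivers above.
- `docs/methods.md` — model, assumptions, defaults, limitations.
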