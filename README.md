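# instarcluster

Determining the larval instar of an insect from morphometric measurements
is a routine but error-prone task in applied entomology: for leaf-mining
pests such as the tomato leafminer *Tuta absoluta* (Lepidoptera:
Gelechiidae), instars look alike, and control measures (entomopathogens,
parasitoid releases) are effective only against specific instars.
`instarcluster` implements an instar-determination pipeline built around
**density-based OPTICS clustering** of three sclerotized head structures —
head capsule length, head capsule width and mandible width (cm) — with
three comparison backends (DBSCAN, *k*-means, Gaussian mixtures with BIC
model selection) and the classical validation battery for instar series.

## The methods in brief

**OPTICS** orders specimens by density reachability. For a point *p* with at
least *minPts* neighbors within radius ε (including itself), the
*core-distance* is the distance to its (*minPts* − 1)-th nearest other point;
the *reachability-distance* of *p* from a processed core point *q* is
max(core-dist(*q*), d(*p*, *q*)). The visit order plus these two distances is
the result; valleys of the reachability profile are clusters. A flat cut at
radius `eps_cl` reproduces DBSCAN's core-point labeling at that radius; the
ξ steep-area method extracts a cluster hierarchy instead. With ε = ∞ the
full structure is computed — ε only caps the neighborhood search.

A candidate partition into instars 1..K (numbered smallest-first) is then
validated against **Dyar's rule**: head-structure sizes grow geometrically
between molts, so the **Brooks–Dyar indices** b_i = x̄_i / x̄_{i−1} should be
roughly constant, the **Crosby indices** C_i = (b_{i+1} − b_i)/b_i should stay
below ~10 % in magnitude, the per-instar size-frequency distributions should
not overlap, and the regression of ln(size, mm) on instar number should be
tight, with growth-rate constant e^slope.

Because raw instar datasets of this kind are rarely deposited, the package
includes a first-class synthetic generator: a truncated trivariate normal
per instar, parameterized by published per-instar means, coefficients of
variation and size ranges for *T. absoluta* (240 larvae in groups of
69/42/35/94), with configurable inter-feature correlation.

## Worked example

```
$ instarcluster generate --out table.csv --seed 1
wrote 240 specimens to table.csv
$ instarcluster cluster --method optics --in table.csv --out-dir run/
4 clusters (sizes (69, 42, 35, 94)), 0 noise
$ instarcluster validate --in table.csv --partition run/partition.csv
...
head_capsule_width_cm  1       69   0.1919 0.0086  0.1755  0.2146  4.4718         NaN           NaN
                       2       42   0.3072 0.0133  0.2776  0.3313  4.3373      1.6009           NaN
                       3       35   0.4970 0.0203  0.4630  0.5433  4.0924      1.6177        0.0105
                       4       94   0.7380 0.0309  0.6765  0.8079  4.1867      1.4850       -0.0821
...
mandible_width_cm: y = 0.433x + -0.512, e^b = 1.542, R^2 = 0.986, RSS = 1.053, df = 238
adjacent-range overlap: False
$ instarcluster compare --in table.csv --seed 1
        optics  dbscan  kmeans   gmm
optics   1.000   1.000   1.000 1.000
dbscan   1.000   1.000   1.000 1.000
kmeans   1.000   1.000   1.000 1.000
gmm      1.000   1.000   1.000 1.000
```

Reading the output: OPTICS at the default *minPts* = 5 splits the 240
specimens into four groups whose sizes match the generated instars
exactly. Head-capsule-width means grow by factors 1.60/1.62/1.49 (the
Brooks–Dyar indices), Crosby indices are ~1–8 %, adjacent size ranges do
not overlap, and ln(mandible width) increases linearly with instar
(R² = 0.986, growth-rate constant e^b = 1.54). All four clustering
backends produce the identical partition (adjusted Rand index 1.0).

The same is available as a library:

```python
from instarcluster import (GeneratorConfig, NeighborhoodParams,
                           generate_instar_dataset, optics_order,
                           extract_clusters_reachability,
                           default_extraction_radius, summarize_instars)
table = generate_instar_dataset(GeneratorConfig(seed=1))
res = optics_order(table, NeighborhoodParams(min_pts=5))
part = extract_clusters_reachability(res, default_extraction_radius(table, 5))
summary = summarize_instars(table, part)
```

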