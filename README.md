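# philopatry

Fine-scale natal philopatry and breeding-site fidelity analysis for
mark-recapture resight data from pinniped breeding colonies.

Long-term tagging programs at breeding colonies record, for each observed
seal, a date, a named beach, an age, and — during the breeding season — the
identity of its mother or pup. Because a female's own birth beach and her
later pupping beaches are both in the record, such data can answer a
question that colony-level philopatry estimates cannot: *how far, within
her colony, does a female give birth from the beach where she herself was
born, and does she keep returning to the same site across breeding
seasons?* This package implements that within-colony analysis end to end
for colonies mapped as a set of named beach segments (tens of meters to a
few kilometers of coastline).

## What it computes

Given a beach registry (centroids in projected UTM meters, region labels,
and rules resolving legacy beach names) and a resight table, the pipeline:

1. **Geo-registry** — resolves aliased/legacy beach names (same-site,
   midpoint, cluster-centroid, sub-area, historical-coordinate, or omitted)
   and builds the symmetric beach-to-beach straight-line distance matrix
   `D[i,j] = ||c_i − c_j||` from centroids, so all displacement values are
   discrete beach-level distances.
2. **Pair extraction** — finds each qualified mother-pup pair: the mother's
   natal beach (first beach observed in her age-0 season) versus her pup's
   first-observed beach that season; immigrant mothers and omitted beaches
   are excluded with reason codes, never silently dropped.
3. **Permutation nulls** — tests whether observed natal-to-pupping (or
   first-to-later pupping) distances are shorter than chance by shuffling
   the beach alignment: with statistic `T` (mean or median pair distance),
   `p = #{T_perm ≤ T_obs} / n_perm` against the one-sided alternative of
   philopatry/fidelity (default `n_perm = 10,000`).
4. **Displacement models** — a median (τ = 0.5) quantile regression of
   distance on maternal age or on the lag in years between pupping events,
   minimizing the check loss `ρ_τ(u) = u(τ − 1{u<0})` *exactly* (every
   optimal line passes through two observations, so all candidate lines are
   scored), with a paired bootstrap for the one-sided slope test; and a
   multinomial (softmax) regression of pup region on mother natal region,
   reported as relative-risk ratios against a baseline region.
5. **Shape diagnostics** — Hartigan's dip statistic (smallest sup-norm
   distance from the empirical CDF to any unimodal CDF, computed exactly by
   a band-feasibility bisection) with a uniform-null Monte-Carlo p-value,
   and Sarle's bimodality coefficient
   `bc = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3)))`.
6. **Synthetic colonies** — a generator with known ground truth (philopatry
   kernel scale λ, per-lag-year median drift, breeding-skip rate, legacy
   aliases, immigrants), so every stage is testable without any field data
   and estimator operating characteristics can be measured.

The study beach registry (52 sites: 40 mapped beaches plus 12 rule-resolved
legacy names; one uninterpretable name excluded) ships in
`philopatry.studymap` with synthetic stand-in coordinates, since the real
centroids are not public.

## Worked example

Simulate a colony at default study-like conditions (40 beaches over ~3.2 km,
70 females, philopatry kernel λ = 400 m) and run all three analyses:

```bash
philopatry simulate --seed 0 --out demo/data
philopatry all --resights demo/data/resights.csv \
               --coords demo/data/beaches.csv \
               --aliases demo/data/aliases.csv \
               --seed 0 --out demo/report
```

`demo/report/natal.json` then contains (abridged):

```
"accounting":       {"n_records": 442, "n_pairs": 120,
                     "exclusion_reasons": {"immigrant": 4}}
"distance_summary": {"n": 120, "mean_m": 316.9, "median_m": 165.0,
                     "q1_m": 82.5, "q3_m": 495.0, "max_m": 1815.0}
"permutation.mean": {"observed_m": 316.9, "null_mean_m": 1069.8,
                     "p_label": "p < 0.0001", "n_perm": 10000}
```

Read: 120 mother-pup pairs qualified (4 immigrant mothers excluded); females
gave birth a mean of 317 m from their natal beach, versus 1070 m expected if
pupping beaches were assigned at random — none of the 10,000 shuffled means
was as small, so fine-scale philopatry is detected at the test's resolution.
The fidelity bundle reports the same machinery for first-versus-later
pupping sites (here mean 67 m, again `p < 0.0001`: the generator's default
site-drift is weak), and the regions bundle gives the 3×3 natal-to-pupping
region flow with relative-risk ratios, e.g. "Northern mothers, Northern vs
Southern pups: RRR 175, p = 1.4e-09" for this strongly philopatric draw.

The same commands run on real data by pointing `--resights`, `--coords`,
and `--aliases` at the program's own tables (columns documented in
`philopatry.records` / `philopatry.geo`).

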