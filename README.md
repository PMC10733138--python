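# exposeg

Exposure segregation from GPS-like mobility traces.

Residential segregation indices ask where people *live*; this package asks
whom they actually *cross paths with*. Given timestamped device pings, it
infers each device's home and socioeconomic status (SES, proxied by the
monthly rent of the home), detects every space–time path crossing between
devices, and measures how strongly SES sorts those real-world encounters.
Because device-level mobility data are privacy-restricted, the package ships
a synthetic-city generator with full ground truth (true homes, rents, venue
visits, and co-locations), so every stage of the pipeline is testable end to
end, and urban-design mechanisms — venue homophily, hub placement — can be
studied in controlled simulation.

It is aimed at computational social scientists and urban/health researchers
who work with mobility traces (or want to prototype against realistic
synthetic ones).

## The measures

**Exposure segregation** of a region is the Pearson correlation between a
resident's SES `x_i` (standardized to unit variance) and the mean SES of the
people they encounter. Two devices are *exposed* when they record pings
within `D = 50` m (great-circle) and `T = 5` min of each other, both strict;
consecutive qualifying ping pairs of a dyad closer than `T` collapse into
one exposure event. Repeated exposures to the same partner are not
upweighted. The index is 0 under random mixing and 1 when people only ever
meet others of identical SES.

With few observed partners per person, the sample correlation against
observed partner means is attenuated (the observed mean is a noisy estimate
of the latent one). The package therefore fits the random-intercept model

    y_ij = a·x_i + b + ε⁽¹⁾_i + ε⁽²⁾_ij,     ε⁽¹⁾ ~ N(0, σ₁²), ε⁽²⁾ ~ N(0, σ₂²)

by REML (own implementation: profiled restricted likelihood over the
variance ratio; cross-checked against `statsmodels.MixedLM` in the tests)
and reports the attenuation-free correlation

    r = a / √(a² + σ₁²).

The **neighbourhood sorting index** (NSI) — the correlation between SES and
home-tract mean SES — is recovered exactly as the special case in which
everyone is "exposed" uniformly to their tract co-residents.

The **bridging index** measures whether a region's hubs (commercial centres)
sit between diverse neighbourhoods: residents are clustered by their nearest
hub, and the index is the size-weighted mean within-cluster Gini of SES
divided by the region-wide Gini — 0 when every catchment is SES-uniform,
1 when every catchment mirrors the whole region.

## Worked example

```python
from exposeg import (CityConfig, generate_city, generate_traces,
                     find_path_crossings, build_ego_records,
                     estimate_exposure_segregation,
                     neighbourhood_sorting_index)

cfg = CityConfig(n_individuals=400, n_tracts=9, n_pois=40, n_hubs=4,
                 n_days=6, venue_homophily=1.0,
                 tract_ses_autocorrelation=0.6, seed=7)
city = generate_city(cfg)
pings, _ = generate_traces(city, compute_truth=False)

edges = find_path_crossings(pings[pings["accuracy_m"] <= 100])
ind = city.individuals.rename(columns={"tract_id": "home_tract_id"})
records = build_ego_records(edges, ind)

naive = estimate_exposure_segregation(records, "naive")
mixed = estimate_exposure_segregation(records, "mixed")
nsi = neighbourhood_sorting_index(ind)
print(f"exposure events: {len(edges)}")
print(f"naive exposure segregation:     {naive.value:.3f}")
print(f"corrected exposure segregation: {mixed.value:.3f}")
print(f"neighbourhood sorting index:    {nsi.value:.3f}")
```

which prints

```
exposure events: 13015
naive exposure segregation:     0.328
corrected exposure segregation: 0.748
neighbourhood sorting index:    0.571
```

Read: in this simulated city, encounters are strongly SES-sorted — a
person's SES predicts the latent mean SES of the people they cross paths
with at r ≈ 0.75. The naive correlation (0.33) understates this because
each resident is only observed with a limited sample of partners; the
mixed-model correction removes that attenuation. Residential sorting alone
(NSI = 0.57) does not capture the additional sorting produced here by
SES-homophilous venue choice.

The numbered scripts under `analysis/` walk the full study — simulation,
home/SES inference audit, network construction with an exhaustive-oracle
spot check, annotation, segregation decompositions, the hub-placement
experiment, and the inferential toolkit — each printing its findings and
writing a small table to `results/`.

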