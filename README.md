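# ecotrap

Spatially explicit, stochastic individual-based simulation of a native
butterfly population exposed to an **ecological trap**: a non-native host
plant (*Thlaspi arvense*) that attracts oviposition but kills every larva.
The package is for population ecologists and invasion biologists who want to
ask how the *fine-grained* spatial arrangement of such a trap — its cover,
patch number, patch size, compactness, and distances to native hosts and to
itself — shapes the joint demographic and evolutionary fate of the consumer.

## The model

Female butterflies (*Pieris macdunnoughii*-like) fly over a grid of
0.25 m × 0.25 m cells for a 54-day season.  Each day a female takes uniform
random-direction steps whose length depends on her current cell (6 cells on
an available host, otherwise 8/10/15 cells in wet/intermediate/dry ground),
until her sampled daily flight budget (truncated-normal, metres) is spent or
her age-dependent daily egg load is laid.  Landing on an available host she
oviposits one egg with probability 0.75 — on the non-native only if she
carries the acceptance allele.

Oviposition preference is a 1-locus/2-allele **Z-linked** trait.  Females
are heterogametic (ZW), so a female's single Z allele comes from her father
and alone sets her phenotype.  The pooled allele frequency is

    p = (2 p_male + p_female) / 3.

Generations turn over annually: eggs survive to adulthood with probability
0.00651 on native hosts and 0 on the trap; female immigrants arrive at 7% of
the surviving female count; lifespans follow ceil(−1/ln x) with
x ~ N(0.86, 0.04) restricted to (0, 1); emergence dates follow a
Beta(1.75, 8.28) density over the season.  Two summary rates are reported
per run:

* **R** — geometric mean of N_t / N_{t−1} (population growth rate),
* **G** — geometric mean of p_t / p_{t−1} (acceptance-allele change rate).

Landscape tools identify 4-connected host patches, compute the compactness
index `shape = 0.25 · perimeter(m) / √area(m²)` (1.0 for any square), exact
periphery-to-periphery distances, and generate controlled scenario maps
(square/elongated/scattered/enlarged trap patches at chosen cover and
placement) plus a calibrated synthetic fixture landscape standing in for the
observed 16.1 ha field site.

## Worked example

```python
import numpy as np
import ecotrap as et

# a synthetic 16.1 ha landscape with the trap at its observed 2.7% cover
base = et.generate_fixture_landscape(seed=1)
print(et.compute_spatial_metrics(base).as_dict())
# {'cover': 0.027, 'patchnum': 63, 'area': 5.571, 'shape': 1.271,
#  'dist': 5.085, 'thdist': 19.644}

res = et.run_replicates(base, et.SimConfig(generations=30, seed=1),
                        replicates=10)
print(f"R = {res.mean_R:.3f} +- {res.sd_R:.3f}")
print(f"G = {res.mean_G:.3f} +- {res.sd_G:.3f}")
# R = 0.992 +- 0.017
# G = 0.999 +- 0.016
```

The trap at its observed abundance depresses growth only slightly (R just
below 1) and the acceptance allele persists (G ≈ 1): the population declines
slowly while selection against acceptance stays weak — the eco-evolutionary
signature of a fine-grained ecological trap.  Raising the cover to 10–20%
(e.g. `generate_scenario_map(base, ScenarioSpec(mode="enlarge", cover=0.2),
rng)`) drives mean R down markedly, and G with it.

A thin CLI mirrors the library: `ecotrap genmap`, `ecotrap metrics`,
`ecotrap simulate`, `ecotrap scenarios`, `ecotrap sensitivity`.

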