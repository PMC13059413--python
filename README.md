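# leadmap

Identification of **informal leaders** in clinical teams from roster-based
advice-seeking surveys, built for social-network-analysis studies in
health-professions education (e.g. an internal-medicine residency with
preceptors and residents).

The package separates two facets of leadership:

* **Leadership-as-Imagined (LAI)** — how strongly a physician rates their own
  leadership on eight 5-point Likert items, two per leadership style
  (transformational, relational, adaptive, resilient);
* **Leadership-as-Done (LAD)** — how central they actually are in the
  directed advice-seeking network, measured by four centrality proxies:

  | style            | proxy metric    | reading                  |
  |------------------|-----------------|--------------------------|
  | transformational | in-degree       | trusted advisor          |
  | relational       | betweenness     | information broker       |
  | adaptive         | out-closeness   | rapid disseminator       |
  | resilient        | in-closeness    | efficient receiver       |

Each raw centrality nᵢₖ is min–max rescaled onto the survey's 1–5 scale, and
a panel of preceptors ranks the importance of the four styles (rank r mapped
to reciprocal values 1.00 / 0.50 / 0.33 / 0.25, summed per style and
normalized into weights wᵢ with Σwᵢ = 1). The composite Leadership Score of
actor *k* is

    LS_k = Σᵢ wᵢ · n_{ik}          (LAD)

and LAI replaces n_{ik} by the mean of the two self-rating items of style
*i*. Actors are classified into four quadrants by the sample means of the
two scores (a score at its cut-off counts as "high"): **established**
(high LAI, high LAD), **humble** (low/high), **aspirational** (high/low) and
**latent** (low/low). A boundary-sensitivity analysis reruns the whole
network pipeline on the residents-only subnetwork and tabulates the quadrant
transitions of each resident.

Because real advice-seeking rosters are usually restricted, the package
ships a synthetic cohort generator (planted-hub Bernoulli digraph, coupled
Likert self-ratings, simulated preceptor rating panel) that reproduces the
statistical structure the analysis assumes, with per-actor planted ground
truth for recovery testing.

## Worked example

Run the full pipeline on a synthetic 68-physician cohort (22 preceptors,
22 R1, 23 R2, 1 R3) and compare the full network with the residents-only
boundary:

```sh
$ leadmap all --out demo_out --seed 7 --boundary both
pipeline complete; artifacts in demo_out
cutoffs: LAI=4.09 LAD=2.37
boundary stability share: 0.783
```

The cut-offs are the cohort means of the two scores: an actor with LAI ≥
4.09 sees themselves as a leader, one with LAD ≥ 2.37 is granted influence
through advice ties. The stability share says that 78.3 % of the 46
residents keep their quadrant when preceptors are removed from the network
and all metrics and cut-offs are recomputed.

`demo_out/` then contains `quadrant_assignments.csv`:

```
actor_id,role,quadrant,lai,lad
P1,preceptor,latent,3.47,2.11
P2,preceptor,established,4.82,3.09
P3,preceptor,established,5.0,3.55
...
```

plus `style_weights.csv` (elicited importance weights; here relational 0.35,
transformational 0.27, adaptive 0.20, resilient 0.18), per-actor
`leadership_profiles.csv`, the 4×4 `quadrant_transitions.csv`, a
`summary.json` with all headline numbers, the LAI–LAD scatter, a sociogram,
and network exports (edge-list CSV, UCINET DL, GraphML).

The same analysis runs on real data from two CSV tables (survey +
preceptor-rating, see `leadmap.survey_ingest` for the schema):

```sh
leadmap all --survey survey.csv --ratings ratings.csv --out results/
```

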