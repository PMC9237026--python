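# trophicstab

Food-web stability analysis for fishing-impact studies: weighted and
unweighted trophic metrics, degree-preserving null models, and a
two-scenario (fishing vs non-fishing) comparison pipeline.

## The problem

Bottom-trawl fisheries reshape marine food webs in two ways at once: a
*fishery* acts as a new top consumer of the caught species, and the
*discard* it returns to the sea becomes a novel basal resource for
scavengers and opportunists. Whether that rewiring erodes the stability of
the whole community is a network question. This package takes a food web —
a directed graph of predator→prey links weighted by diet proportions — and
measures structure and stability in both an unweighted (topology-only) and
a weighted (diet-informed) version, for a baseline web and its
fishery-augmented variant:

- **Trophic level (TL)** — basal resources have TL = 1 and a consumer sits
  one level above the (diet-weighted) mean of its prey; stacking the
  definition over all nodes gives the linear system `(I − Qᵀ)·TL = 1`,
  where `Q` is the prey-by-predator diet matrix whose consumer columns sum
  to 1. Mean TL (mTL) is among the most fishing-sensitive summary
  statistics of a web.
- **Omnivory** — the fraction of nodes feeding on prey more than a full
  trophic level apart (unweighted), or the mean diet-weighted variance of
  prey TLs over consumers (weighted).
- **Modularity** — directed Newman modularity
  `Q = (1/m)·Σᵢⱼ [wᵢⱼ − sᵢᵒᵘᵗ sⱼⁱⁿ / m]·δ(cᵢ,cⱼ)`, maximized by simulated
  annealing over partitions (single-node moves, merges and splits with
  Metropolis acceptance), so it works for directed *and* weighted webs
  without getting stuck in local optima.
- **Quasi-sign-stability (QSS)** — the proportion of random community
  (Jacobian) matrices, with sign pattern fixed by the topology (prey
  benefit predators, predators harm prey, every node self-limited), whose
  eigenvalues all have negative real parts.

Metric differences between the two scenarios are judged against **null
ensembles** built with the curveball algorithm (degree-preserving trades of
prey between predator pairs) plus a column-sum-preserving shuffle of diet
weights, compared with the two-sample Anderson–Darling test, an effect
size (difference of ensemble medians over the pooled standard deviation),
and a chi-squared test on stable/unstable QSS counts.

A niche-model generator produces synthetic webs with the statistical
structure of a speciose coastal web (~80 nodes, ~400 links, few basal
species, 4–7 trophic levels) and wires a fishery + discard scenario onto
them, so the entire pipeline is exercisable without any data download.

## Worked example

```bash
$ trophicstab simulate --s 40 --c 0.08 --seed 7 --out-dir demo
wrote FoodWeb('non-fishing', nodes=40, links=118) and FoodWeb('fishing', nodes=42, links=146) under demo

$ trophicstab metrics --web demo/nonfishing.csv --nodes demo/nonfishing_nodes.csv --weighted
{
  "mTL": 3.6706593771416607,
  "max_TL": 5.601850418220648,
  "omnivory": 0.2315262368608579,
  "tl_class_pct": {"top": 7.5, "intermediate": 87.5, "basal": 5.0},
  ...
}

$ trophicstab qss --web demo/nonfishing.csv --n 1000 --seed 3
{
  "proportion_stable": 0.504,
  "n_samples": 1000,
  "n_stable": 504,
  "se": 0.01581088232832058,
  ...
}
```

The simulated baseline web has a mean trophic level of 3.67 with a top
predator at TL 5.6, 5% basal nodes, and roughly a quarter of its nodes
feeding across more than one trophic level — the profile of a speciose
marine shelf community. Half of its randomly parameterized Jacobians are
locally stable (QSS 0.504 ± 0.016).

The same analysis runs end-to-end from a config file:

```bash
trophicstab run --config run.yaml --out-dir results/
```

with `run.yaml` naming either two edge-list files or a synthetic recipe,
the ensemble sizes, seeds, and weightings. Outputs are per-web metric
JSONs, one CSV per null ensemble, and a comparison report (JSON + CSV)
with one row per metric × weighting and the QSS comparison. Reports are
bit-identical across reruns with the same config.

Edge lists are plain CSV (`predator,prey,weight` — column names remappable)
with an optional node table (`id,label,kind`); webs export to GraphML with
weight and kind attributes. The library surface (`trophicstab.FoodWeb`,
`trophic_levels`, `find_best_partition`, `qss`, `null_distribution`,
`compare_ensembles`, `build_fishing_web`, `niche_model`, …) is importable
without the CLI.

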