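# morphnet

Individual morphological brain-network analysis over the 68-region
(34 per hemisphere) Desikan–Killiany cortical parcellation.

Each subject's network is built by z-scoring five regional morphometric
features (cortical thickness, gray-matter volume, surface area, mean
curvature, fold index) across regions, concatenating them into one
feature vector per region, and taking the Pearson correlation of every
region pair — a 68×68 symmetric matrix with 2278 unique weighted edges
per subject. On top of that the package provides:

- **Weighted graph metrics** per subject: global/local efficiency
  (Latora–Marchiori, with the cube-root weighted local variant),
  weighted betweenness centrality (Brandes, lengths = 1/w), normalized
  BC (mean 1 across regions), and modularity as the best weighted
  Newman Q over seeded community-detection rounds.
- **Hub identification**: a subject's hubs are regions with
  nBC > mean + SD; group consensus hubs are regions that are individual
  hubs in at least 30% of subjects (inclusive threshold).
- **Edge-wise group statistics**: per-edge outlier exclusion, rank
  transform of the pooled values (mean ranks for ties), Levene-gated
  pooled/Welch two-sample t-tests, Benjamini–Hochberg FDR across the
  2278 edges, and a four-way classification of significant edges
  (decrease/increase × positive/negative correlation).
- **MMSE screening**: subjects with MMSE < 28 are labeled patients;
  inside the 28–30 zone, global efficiency, mean local efficiency and
  mean BC vote against decision thresholds.
- **A synthetic cohort generator** that draws subjects from
  positive-definite group correlation templates (with per-edge effect
  implants, loadable from the packaged reference table of altered
  connections) and couples MMSE to each subject's realized global
  efficiency, so the whole pipeline is testable without external data.

Packaged reference data (`src/morphnet/data/`): the atlas table with
abbreviations/lobes/classes, a schematic centroid layout for viewer
exports, the published 52-row edge-alteration table, and the published
per-region consensus-hub fractions for both groups.

## CLI

```sh
# generate a synthetic cohort fixture set (wide TSVs + cohort TSV)
morphnet simulate --n-nc 20 --n-ad 20 --seed 1 --out data/sim

# individual stages
morphnet build-net --in data/sim --out runs/nets
morphnet metrics   --in data/sim --out runs/metrics.tsv --rounds 100
morphnet compare   --in data/sim --out runs/edges.tsv --tails two
morphnet hubs      --in data/sim --out runs/hubs --threshold 0.30
morphnet screen    --in data/sim --out runs/screening.tsv

# everything end to end (simulate or --in, YAML config optional)
morphnet all --simulate --seed 1 --rounds 100 --out runs/full
```

`morphnet all` writes per-subject networks, scalar and nodal metric
tables, the edge comparison with FDR and change classes, per-group
consensus-hub tables, the screening table, BrainNet-Viewer-style
`.node`/`.edge` files, and a `summary.json` carrying the config hash,
seed and headline counts. Re-running with the same config reproduces
the numeric outputs byte for byte.

Input format: one wide TSV per feature in the `aparcstats2table`
layout (`subject`, then `lh_bankssts_<feature>`, …), or a long TSV
with columns `subject, region, feature, value`, plus a cohort TSV
(`subject, group, age, sex, mmse, cdr`).

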