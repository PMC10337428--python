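# lifetriage

Anticipatory triage ranking for mass-casualty incidents. Instead of a
static category, each casualty gets a modelled time course of their
expected condition — a falling sigmoid whose starting level is set by
current vital signs (weighted Revised Trauma Score, RTS) and whose
decompensation timing/speed is set by anatomical injury severity (New
Injury Severity Score, NISS). The time at which the curve crosses a
small death threshold ("survival time without treatment") ranks
casualties for treatment priority and can also be banded into the four
classic triage categories.

The package contains:

- `lifetriage.scores` — RTS coding/weighting, T-RTS, NISS, and
  validated patient records.
- `lifetriage.model` — the sigmoidal time-course model, closed-form
  survival time, trajectories, and cohort ranking.
- `lifetriage.triage` — START, T-RTS-based triage, and survival-time
  (LIFE) triage, plus a cohort-wide runner.
- `lifetriage.generator` — semisupervised synthetic cohort generation:
  enumerate realistic 1–3-injury combinations from a 14-trauma-type ×
  13-body-location catalog, drop anatomically impossible combinations,
  and attach NISS-banded randomized vital signs with dependency rules.
- `lifetriage.analytics` — Gower distance for mixed clinical features,
  PAM (k-medoids) clustering with silhouette-based k selection, t-SNE
  embedding from the precomputed distance matrix, triage
  cross-tabulations, and cluster-vs-consensus comparison.
- `lifetriage.io` / `lifetriage.scenario` / `lifetriage.cli` — CSV/JSON
  patient tables (scores re-validated on read), the bundled 10-casualty
  demo scenario, and the command-line interface.

The default trauma catalog, vital-parameter bands, and triage-band
thresholds are documented stand-ins calibrated against the qualitative
constraints of the method (see module docstrings); all are replaceable
via CSV/JSON configuration.

## CLI

```sh
# generate a seeded synthetic cohort (optionally subsampled)
lifetriage generate --seed 42 --max-patients 10000 --out cohort.csv

# classify with START / RTS triage / LIFE triage
lifetriage triage --in cohort.csv --out triaged.csv

# rank by survival time without treatment
lifetriage rank --in cohort.csv --out ranked.csv

# run the bundled 10-casualty demo scenario
lifetriage simulate --out-dir demo/

# Gower + PAM clustering and 2-D embedding
lifetriage cluster --in cohort.csv --k 6 --seed 1 --subsample 2000 \
    --out-prefix results/run1

# compare one cluster against consensus-triaged patients
lifetriage compare --in cohort.csv --clusters results/run1_clusters.csv \
    --focus-cluster 3 --out compare.json
```

Model constants and triage thresholds can be overridden with
`--config config.json`, e.g.
`{"model": {"t_ref_min": 720}, "thresholds": {"black_max_min": 30}}`.

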