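# morphprint

Disease fingerprints from regional brain morphometry.

`morphprint` implements a normative-modelling pipeline for case–control
regional brain volumetry and cortical thickness:

1. **Registry** — an 89-region parcellation inventory (34 cortical,
   23 subcortical, 22 hippocampal subfields, 10 amygdalar nuclei) with
   canonical labels, FreeSurfer-spelling aliases, hemisphere availability
   and normalization parents.
2. **I/O** — a canonical long-format TSV plus convenience importers for
   FreeSurfer 6.0 stats dialects (`aseg.stats`, `?h.aparc.stats`,
   hippocampal-subfield and amygdalar-nuclei volume tables).
3. **Preprocessing** — age correction of every measurement with per-key
   regression slopes fitted on the control cohort, then normalization of
   volumes by intracranial volume (or by whole hippocampus / whole amygdala
   for subfields and nuclei). Thickness is age-corrected only.
4. **Fingerprint** — per-key two-sided Student's t screening (pooled
   variance; Welch optional) and a bilateral-significance filter: a
   region×metric pair enters the fingerprint only if significant with
   concordant direction (atrophy vs. dilation) in both hemispheres
   (single test for midline regions).
5. **Scoring** — per-subject z-scores against the control reference for
   every fingerprint key; an entry counts as an outlier when the
   direction-signed z exceeds the threshold (default 2 SD) in either
   hemisphere. Subjects whose outlier count exceeds
   `control mean + 2·SD` are classified at risk.
6. **Neuropsych** — cognitive composite scores (mean of available subtest
   Z-scores), decline flags against a premorbid estimate, and Pearson
   correlations between subtest scores and outlier counts.
7. **Group×age regression** — `value ~ age + group + age:group` OLS with
   per-coefficient inference and the overall F test.
8. **Synthetic cohorts** — a fully parameterized three-cohort generator
   (control / disease / exposed) with ICV-coupled volumes, linear age
   drift, correlated hemispheres, parent-fraction subfields, per-subject
   "spike" effects with a ground-truth ledger, and cognition scores with
   configurable correlation against true atrophy burden. This makes the
   entire pipeline testable end to end with no external data.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with the calibration/recovery criteria
(null-calibration of the screening test, oracle equivalence of every
statistic against brute-force implementations, 200-replicate recovery of a
configured 27 % regional deficit, and known-prevalence classification
checked against the generator's truth ledger). The full run takes a few
minutes on one CPU.

## CLI

```sh
# generate synthetic cohorts (writes long TSVs, cognition tables, truth ledger)
morphprint simulate --seed 7 --out runs/sim

# derive a fingerprint: age-correct + normalize both cohorts, screen, filter
morphprint derive --controls runs/sim/controls.tsv --cases runs/sim/cases.tsv \
    --out runs/fp

# score another cohort against the stored fingerprint
morphprint score --fingerprint runs/fp/fingerprint.tsv \
    --controls runs/sim/controls.tsv --cohort runs/sim/exposed.tsv \
    --out runs/score

# cognition: composites, decline rate, correlation with outlier counts
morphprint neuropsych --anam runs/sim/anam.tsv --wrat runs/sim/wrat.tsv \
    --profiles runs/score/profiles.tsv --out runs/np

# age x group interaction on one region
morphprint interaction --table runs/sim/morphometry.tsv \
    --region Inf-Lat-Vent --hemisphere left --case-group exposed --out runs/ix
```

Every run writes a `manifest.json` with input/output SHA-256 digests and
stage timings; deterministic stages reproduce digests exactly. Exit codes:
0 success, 2 validation error, 3 statistical degeneracy.

## Data formats

The canonical interchange format is a tab-separated long table:

```
subject_id  group  age  sex  cohort_tag  icv  region  hemisphere  metric  value
```

with `group ∈ {control, AD, exposed}`, `hemisphere ∈ {left, right, none}`
(`none` for midline/global regions) and `metric ∈ {thickness, volume}`.
Values are written with full precision so write→read round trips are
bit-exact. Missing cells are allowed; group statistics use
pairwise-complete subjects per key, and nothing is skipped silently.
Fingerprints, age models, control references, profiles and the simulation
config (YAML) all round-trip through flat text files.
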