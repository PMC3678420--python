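# pmdtune

Tuning analysis and population decoding for premotor reach/grasp
spike-train sessions, with a synthetic session generator for validation.

The pipeline takes per-neuron spike timestamps plus a trial event table
(cue-light on/off times and a 4-way action label) for a paired session —
one reaching block (4 directions) and one grasping block (4 objects)
sharing a neuron roster — and:

1. **simulate** — generates synthetic session pairs with the same trial
   clock and a planted ensemble of reach-only / grasp-only / both /
   untuned neurons (piecewise-constant inhomogeneous Poisson rates), so
   every downstream stage can be validated by parameter recovery;
2. **preprocess** — aligns spikes to cue onset, cuts a half-open
   analysis window (default −0.5 s to +1.7 s), bins firing rates at
   100 ms, and extracts binary spike indicators every 10 ms;
3. **stats** — one-way ANOVA screens: movement-vs-rest task-relatedness
   and per-bin across-action tuning (≥ 2 significant movement bins);
4. **infotheory** — plug-in mutual information between each neuron's
   pooled spike indicators and the action label, per task; a
   cumulative-90% threshold on the descending MI list defines the tuned
   subset; crossing the two tasks' thresholds categorizes each neuron
   as reach-only, grasp-only, both, or untuned; contribution tables
   report each category's share of a task's total information;
5. **decode** — one-vs-one RBF-kernel SVM decoding of the action from
   binned rates (features: neuron subset × trailing bins, standardized;
   C and γ by stratified 2-fold cross-validated grid search), with two
   experiments: full ensemble vs tuned subset vs top-10 by MI, and
   single-property subsets with vs without the both-tuned neurons.

## CLI

```sh
# simulate a session pair to plain-text tables (spikes.tsv, events.tsv, session.json)
pmdtune simulate --task reach --neurons preset:7,5,9,10 --seed 1 --out reach-session
pmdtune simulate --task grasp --neurons preset:7,5,9,10 --seed 1 --out grasp-session

# MI profile, thresholds, categories, contribution shares
pmdtune analyze mi --reach reach-session --grasp grasp-session

# decoding experiments
pmdtune analyze decode --reach reach-session --grasp grasp-session --experiment ensembles

# full pipeline from a YAML config (see pmdtune.pipeline.RunConfig fields)
pmdtune run --config config.yaml
```

`pmdtune run` writes `stats-report.tsv`, `mi-profile.tsv`,
`contributions.tsv`, `decoding-results.tsv`, `summary.json` and figures
(PSTH panels, MI bars, decoding accuracies) to the configured output
directory; re-running the same config reproduces every output byte for
byte.

## Acceptance

Acceptance is property-based (`tests/test_acceptance.py`): MI oracle
equivalence and closed forms, the cumulative-threshold rule and its
coverage invariant, ≥ 90% planted-category recovery on seeded synthetic
sessions, ANOVA null calibration and power, decoding chance floors and
subset orderings, the qualitative contribution pattern, and end-to-end
determinism.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end self-check and writes the (empty — no numeric
targets are defined for this package) acceptance report.
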