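# psaphen

Model-based stratification of psoriatic-arthritis (PsA) patients from
baseline clinical features, with stability assessment and
responder-endpoint analysis by phenotype.

PsA is clinically heterogeneous — joint, entheseal, dactylitic and skin
involvement combine differently from patient to patient — and treatment
response varies with that presentation. `psaphen` is aimed at
biostatisticians and clinical researchers who want to (1) identify
homogeneous patient phenotypes in a pooled trial-style baseline table,
(2) check that the clustering is stable, and (3) compare responder rates
across phenotypes over follow-up.

## What it computes

**Phenotype discovery.** Patients are modelled with a finite mixture over
mixed-type features,

```
h(y | φ) = Σ_{k=1..K} π_k f_k(y | θ_k)
```

with conditionally independent features within a component (Gaussian for
continuous, multinomial for binary/categorical). Parameters are fitted
by multi-restart EM; the number of phenotypes is chosen by a BIC grid
search over K = 2..10 with an elbow rule (stop where the decrease of BIC
becomes minimal for all larger K).

**Stability.** Monti-style consensus clustering: repeated 80% subsampling
and refitting accumulate a consensus matrix
`C(i,j) = Σ_t M_t(i,j) / Σ_t I_t(i,j)`, the fraction of co-sampled runs
in which patients i and j cluster together.

**Profiles and endpoints.** Per-phenotype descriptive statistics
("Table 1"-style), cluster-ordered heatmap layouts, and responder rates
(MDA, DAPSA-LDA, TJC50/SJC50, ACR50, and HAQ-DI/pain/FACIT-F MCIDs) by
phenotype and week, as observed or under non-responder imputation with
multiple imputation (NRI-MI) for pandemic/geopolitical missingness.

**Synthetic cohorts.** Patient-level trial data are not public, so the
package ships a generator whose defaults emulate the published
five-phenotype baseline structure (mixing proportions 0.403 / 0.208 /
0.140 / 0.138 / 0.111 and the tabulated per-phenotype feature
distributions), including planted high-missingness and collinear
features and a longitudinal response model. See `docs/methods.md` for
the full model description.

## Worked example

```python
import numpy as np
import psaphen as pp

config = pp.GeneratorConfig(n_patients=1119, seed=1)
cohort, truth = pp.generate_baseline(config)
prep = pp.prepare_cohort(cohort, config.schema())
print(f"loaded {prep.n_loaded} patients; dropped features:",
      [f for f, _ in prep.report.dropped_features])
print(f"complete patients: {len(prep.cohort)} ({prep.retention_pct:.1f}%)")

table = pp.select_k(prep.encoded, seed=1, n_restarts=10)
print("BIC by K:", {k: round(v) for k, v in table.bic_by_k.items()})
print("selected K =", table.selected_k)

model = pp.MixedMixture(n_components=5, n_restarts=10, random_state=1).fit(prep.encoded)
print("mixing weights:", np.sort(model.weights_)[::-1].round(3))
col = list(prep.encoded.columns).index("tjc68")
print("TJC means by component:", np.sort(model.means_[:, col]).round(1))
```

prints

```
loaded 1119 patients; dropped features: ['facit_f', 'tjc68_v2', 'sjc66_v2', 'pain_vas_v2']
complete patients: 1047 (93.6%)
BIC by K: {2: 70225, 3: 69037, 4: 68687, 5: 68431, 6: 68675, 7: 68913, 8: 69150, 9: 69402, 10: 69654}
selected K = 5
mixing weights: [0.415 0.184 0.155 0.125 0.121]
TJC means by component: [10.2 21.2 25.  25.3 45.8]
```

Reading the output: the cleaning stage drops the one feature with > 20%
missingness and the three collinear duplicates, then removes incomplete
patients (93.6% retained). BIC decreases steeply up to K = 5 and rises
afterwards, so the elbow rule selects five phenotypes. The fitted mixing
weights recover the generating proportions (0.403 … 0.111) to within
sampling error at n ≈ 1050, and the component TJC means recover the
generating means (10.1, 20.0, 24.7, 25.3, 46.6) — the most active
phenotype sits near 46 tender joints.

The same pipeline is available from the shell:

```sh
psaphen simulate --n 1119 --seed 1 --out-baseline base.csv \
    --out-visits visits.csv --out-schema schema.yaml
psaphen select-k base.csv --schema schema.yaml --grid 2:10 --out ksel.csv
psaphen fit base.csv --schema schema.yaml --k 5 \
    --out-params params.json --out-labels labels.csv
psaphen consensus base.csv --schema schema.yaml --k 5 --iters 200 \
    --out-matrix consensus.csv --out-summary stability.json
psaphen profile base.csv --schema schema.yaml --labels labels.csv --out profile.json
psaphen endpoints visits.csv --labels labels.csv --analysis nri-mi --out rates.csv
```

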