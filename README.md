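# qcscore

Quantitative continuous scoring (QCS) for membrane-marker
immunohistochemistry.  Instead of ordinal pathologist categories
(IHC 0/1+/2+/3+), the package quantifies target expression as continuous
per-cell optical densities (OD) of the DAB chromogen, derives patient-level
readouts — OD quantiles, % OD-positive cells, positive-cell densities,
binary and continuous **spatial proximity scores** (bSPS/cSPS, which model
the bystander effect of antibody–drug conjugates by crediting cells near an
OD-positive neighbor), and stromal-TIL density — and then searches for
survival- and response-stratifying cut points with the full supporting
machinery: readout consolidation, bootstrap-stabilized cut-point
optimization under a minimum-prevalence constraint, and n-times repeated
k-fold cross-validation with permutation-based empirical log-rank
p-values.

It is written for computational pathology and biomarker teams who have
per-cell measurements (or posterior maps from an upstream segmentation
model) and clinical endpoints, and who want the scoring and statistics
layer to be exactly reproducible.  A synthetic cohort generator with
pixel-level ground truth makes every stage testable without any study
data.

## The scoring model in brief

For tumor cell `i` with membrane OD `OD_i`, sample size `N`, and
neighborhood `N_i^r` (cells `j ≠ i` with centroid distance `d_ij ≤ r`):

- `%positive(t) = 100 · #{i : OD_i ≥ t} / N`
- `density(t) = #{i : OD_i ≥ t} / area_epithelium` (cells/mm²)
- `bSPS(r, t) = 100 · #{i : OD_i ≥ t or ∃ j ∈ N_i^r with OD_j ≥ t} / N`
- `cSPS_i(r) = (OD_i + Σ_j w_ij OD_j) / (1 + Σ_j w_ij)`, `w_ij = 1 − d_ij/r`,
  aggregated per patient by mean or quantile

with `r ∈ {10, 25, 50, 75}` µm and 17 OD thresholds from 6 (faint) to 120
(very strong); both SPS forms reduce exactly to their non-spatial
counterparts as `r → 0`.  Patients with a readout value ≥ an optimized cut
form the biomarker-positive group; cuts are chosen to maximize
positive-group ORR or the PFS log-rank chi-square, subject to both groups
keeping ≥ 20% prevalence, and stabilized as the modal optimum over 50
bootstrap resamples.  Cross-validated significance comes from a
permutation test, because pooled cross-validated KM curves violate the
independence assumptions of the standard log-rank test.

## Worked example

```python
import qcscore as q

# a 40-patient synthetic cohort with a planted biomarker
cfg = q.SimulationConfig(n_patients=40, cells_per_patient=(200, 500), seed=7)
samples, clinical = q.simulate_cohort(cfg)

sample = samples[0]
print(round(q.pct_od_positive(sample, 6), 1))   # 70.4  (% cells with OD >= 6)
print(round(q.bsps(sample, 50, 6), 1))          # 79.0  (+ cells near a positive)
print(round(q.csps(sample, 25, "mean"), 2))     # 19.66 (neighborhood-weighted OD)

values = clinical["planted_value"].to_numpy()
cut = q.bootstrap_cutpoint(values, clinical, target="logrank", seed=1)
res = q.stratify(values, cut, clinical)
print(round(cut, 1))                            # 44.7
print(round(res.high.prevalence_pct, 1))        # 55.0
print(round(res.logrank_p, 4))                  # 0.0004

perm = q.permutation_pvalue(values, clinical,
                            q.CrossValConfig(k=5, n_repeats=10,
                                             m_permutations=99, seed=1))
print(round(perm.p_value, 2))                   # 0.02
```

The optimizer lands a cut at 44.7% OD-positive cells: the 55%-prevalence
positive group's PFS separates from the rest at log-rank p ≈ 4e-4 on the
training set, and the overfitting-resistant cross-validated permutation p
is 0.02 — a small cohort (n = 40), so the recovered cut sits below the
generator's planted boundary of 60; the grouping it induces differs from
the planted one by a handful of borderline patients.

The same pipeline runs from the shell:

```bash
qcs simulate --seed 7 --n-patients 40 --out run/
qcs features --cells run/cohort/cells.parquet --tils run/cohort/tils.parquet \
    --areas run/cohort/areas.csv --out run/
qcs consolidate --in run/readouts.parquet --rho 0.99 --out run/
qcs stratify --readouts run/readouts.parquet --clinical run/cohort/clinical.csv \
    --readout pctpos_od6 --target logrank --out run/
qcs crossval --readouts run/readouts.parquet --clinical run/cohort/clinical.csv \
    --readout pctpos_od6 --k 5 --n 30 --m 199 --out run/
```

or end to end from one YAML config with `qcs run --config pipeline.yaml
--out run/`; every run writes a `manifest.json` with a config hash and all
seeds.

An imaging front-end is included for ROI inputs: `deconvolve_dab` (H-DAB
color deconvolution to a per-pixel OD map), `segment_cells` (seeded
watershed on membrane posteriors, with 2–4 px membrane bands, nuclei at
posterior ≥ 0.5, cytoplasm as remainder), `measure_compartment_od`, and
the concordance metrics (Dice, center F1, ASSD, OD Pearson r) used to
validate it.  See `docs/methods.md` for the full model description.

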