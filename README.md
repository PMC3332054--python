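# rasosig

Transcriptional-signature analysis of PBMC expression profiles for
RASopathy mutation groups.

RASopathies are developmental disorders caused by germline mutations in
RAS–MAPK pathway genes. Bulk expression profiles of peripheral blood
mononuclear cells (PBMCs) from mutation carriers — here, four groups:
healthy controls and carriers of *PTPN11*, *SOS1* or *SHOC2* mutations —
carry gene-specific transcriptional signatures that can discriminate each
mutation group from controls. `rasosig` implements the complete analysis
as a reusable, tested pipeline for anyone working with bead-array-style
expression matrices and small case/control cohorts:

* **Preprocessing** — per-sample mean scaling and log2 transformation,
  detection-p-value filtering, removal of probes correlated with age, sex
  or the differential leukocyte count, and log2-ratio transformation
  against the control-group mean.
* **Signature selection** — a probe enters the signature for a comparison
  iff |mean case Log₂Ratio| > 0.5 **and** t-test *P* < 0.01 **and**
  |SNR| > 0.5, where SNR = (x̄_case − x̄_ctrl)/(s_case + s_ctrl) is the
  Golub signal-to-noise statistic.
* **Permutation FDR** — case/control labels are shuffled (2,000
  permutations by default), the triple test is re-run, and the
  false-positive fraction is estimated as mean null hits / observed hits.
* **Leave-one-out classification** — per held-out sample, all four
  signatures are re-derived on the remainder and the sample is scored by
  weighted voting, score = Σ w_g (x_g − b_g)/Σ|w_g| with w_g the training
  SNR and b_g the midpoint of the training group means; group separation
  of scores is t-tested.
* **Data mining** — hypergeometric gene-set over-representation against
  user-supplied GMT collections, and TF/target circuit detection (TF in
  the signature plus a binomially biased direction split of its targets).
* **Exploration** — hierarchical clustering of samples with per-cluster
  Fisher enrichment in group labels, Newick dendrogram export, and a
  signature-blocked log2-ratio heatmap.
* **Synthetic data** — a generator that emulates the study design (20,589
  probes; 21/17/6/5 samples) with planted signatures,
  confounder-correlated probes and detection dropout, so every stage is
  testable without access to patient data.

## Worked example

```python
import rasosig as rs

cfg = rs.SimulationConfig(n_probes=4000,
    signature_spec={"PTPN11": rs.SignatureSpec(150, 1.0),
                    "SOS1": rs.SignatureSpec(40, 1.0),
                    "SHOC2": rs.SignatureSpec(90, 1.0)},
    seed=17)
ds = rs.simulate(cfg)

ratios, logged, report = rs.preprocess(ds.matrix, ds.samples)
print(f"probes: {report.n_input_probes} -> detected {report.n_detected} "
      f"-> unconfounded {report.n_after_confound_removal}")

sig = rs.select_signature(ratios, ds.samples, ["PTPN11"])
print(f"PTPN11 signature: {len(sig)} probes")

fdr = rs.permutation_fdr(ratios, ds.samples, ["PTPN11"],
                         n_permutations=200, seed=17)
print(f"permutation FDR: {100 * fdr.fdr_estimate:.2f}%")

scores, _ = rs.loo_classify(ratios, ds.samples)
sep = rs.score_separation(scores, "PTPN11", ("PTPN11", "control"))
print(f"LOO separation PTPN11 vs control: t-test P = {sep.t_p:.2e}")
```

prints

```
probes: 4000 -> detected 1381 -> unconfounded 867
PTPN11 signature: 152 probes
permutation FDR: 1.17%
LOO separation PTPN11 vs control: t-test P = 1.59e-32
```

Reading: of 4,000 simulated probes, 1,381 are reliably detected and 867
survive the confounder screen; the triple criterion recovers a 152-probe
PTPN11 signature (150 were planted, some lost to the confounder screen,
a few noise probes gained — the permutation estimate puts the
false-positive content at ~1%); and on leave-one-out scores the PTPN11
group separates cleanly from controls.

The same pipeline is scriptable from the shell:

```sh
rasosig simulate --out data/ --n-probes 4000 --seed 17
rasosig run --config pipeline.yaml          # all stages, full run directory
rasosig select --config pipeline.yaml --case PTPN11
rasosig fdr --config pipeline.yaml --case PTPN11 --n-perm 2000 --seed 17
rasosig loo --config pipeline.yaml
rasosig enrich --config pipeline.yaml --gmt kinase_substrates.gmt
rasosig cluster --config pipeline.yaml --newick tree.nwk
```

`rasosig run` writes every intermediate artifact (signature TSVs, FDR
JSONs with full null distributions, LOO scores, enrichment tables,
dendrogram, heatmap) plus a manifest with the seed, a parameter hash and
the SHA-256 of every output; reruns with the same configuration are
byte-identical.

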