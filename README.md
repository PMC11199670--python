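# fumamap

Quantitative Raman micro-spectroscopy mapping of the oncometabolite
**fumarate** in single cells and tissue sections.

Loss of fumarate hydratase (FH) — as in hereditary leiomyomatosis and
renal cell cancer — makes fumarate accumulate to tens of millimolar.
Because fumarate has an unusually large Raman cross-section, label-free
confocal Raman imaging can detect and spatially resolve it: the
symmetric CO₂⁻ stretch at **1401 cm⁻¹** sits in a valley of the cellular
fingerprint spectrum and its integrated intensity grows linearly with
concentration. `fumamap` implements the full analysis chain for this
kind of experiment, together with a synthetic forward model so every
stage can be validated against exact ground truth:

* **Calibration** — the flat-baseline band area over 1399–1419 cm⁻¹
  (local baseline: mean counts over 1324–1379 cm⁻¹), in
  counts·cm⁻¹·s⁻¹, regressed on concentration. The slope is the
  sensitivity *S* (default 19.2 counts·cm⁻¹·s⁻¹·mM⁻¹); the limit of
  detection is the smallest concentration at which the dilution series
  can no longer be fitted with a horizontal line (nested-model F-test,
  α = 0.05).
* **Per-pixel quantification** — cosmic-ray removal, iterative
  polynomial baseline subtraction (order 4, 7 iterations, tolerance 15
  counts ≈ 2× the noise floor), band integration and inversion
  c = (I − b)/S; alternatively a Gaussian peak fit without baseline
  subtraction. Concentration histograms use 5 mM bins normalised by
  pixel count.
* **Compartment analysis** — k-means with Manhattan distances on
  mean-centered spectra; cluster loadings are assigned to substrate,
  nucleus, membrane, cytoplasm and mitochondria via marker bands
  (cytochrome-C 748/1127/1585 cm⁻¹ → mitochondria, DNA 785 cm⁻¹ →
  nucleus, lipid 1301/1445 cm⁻¹ → membrane). Per-compartment mean ± SD
  concentrations are background-corrected by subtracting the
  FH-proficient control, and compartment differences are tested by
  one-way ANOVA.
* **Classification** — PLS-DA (7 latent variables, venetian-blinds
  cross-validation with 10 splits, every-fourth-spectrum validation
  split) separates FH-proficient from FH-deficient genotypes;
  VIP scores rank the wavenumbers driving the separation. Tissue scans
  are genotyped by whether the majority of pixels exceed the LOD.

## Worked example

Run the end-to-end pipeline on a synthetic FH-deficient (clone 19) cell
phantom with its FH-proficient control:

```python
from fumamap.io import RunConfig, run_pipeline

result = run_pipeline(RunConfig(out_dir="out", seed=1))
print(result["summary"])
print(result["tables"]["case"][0].table.round(1))
print(result["corrected"].table.round(1))
```

prints (seed 1):

```
{'sensitivity': 19.168, 'r_squared': 0.9975, 'lod_mM': 10.0,
 'anova_F': 100.0, 'anova_p': 4.9e-38, ...}

              mean_mM  sd_mM    n        |   corrected mean_mM
substrate         0.6    6.8  920        |        1.0
nucleus           5.0    7.0   98        |        6.0
membrane         15.2    7.8  140        |       11.3
cytoplasm        21.5    8.0  391        |       18.9
mitochondria     33.4    7.8   51        |       27.6
```

The calibration slope recovers the configured sensitivity (19.2
counts·cm⁻¹·s⁻¹·mM⁻¹) to 0.2 %, the LOD at the 0.3 s reference dwell is
10 mM (it drops to ~4 mM at 5 s dwell), apparent concentrations rise
monotonically from nucleus to mitochondria, and subtracting the control
column recovers the true fumarate levels (generator truth
5/10/18/27 mM for nucleus/membrane/cytoplasm/mitochondria) within the
method's bias. The ANOVA confirms that cytoplasm and mitochondria
differ from the membrane far beyond chance.

The same stages are available as a CLI:

```bash
fumamap simulate --preset KO19 --seed 1 --out phantom/
fumamap calibrate --dwell 5 --concs 0,10,20,30,40,50 --out cal.json
fumamap quantify phantom/map.npz --model cal.json --out quant/
fumamap segment phantom/map.npz --k 6 --out seg/
fumamap report --seed 1 --out report/
fumamap classify --seed 0 --out clf/
```

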