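# ctcev

Automated enumeration of **circulating tumor cells (CTCs)** and
**tumor-derived extracellular vesicles (tdEVs)** from CellSearch-style
multi-channel fluorescence image archives, plus the downstream biostatistics
that turn those counts into prognostic biomarkers — all exercised on
synthetic data with known ground truth.

## The problem

One 7.5 mL blood draw, after EpCAM immunomagnetic enrichment, is imaged as a
cartridge of 144–180 four-channel frames (DNA/DAPI, Marker1/FITC,
CK-PE, CD45-APC). A CTC is a cytokeratin-positive, nucleated, CD45-negative
object larger than 4 µm; a tdEV is a cytokeratin-positive, CD45-negative
particle *without* a nucleus, present at roughly 20× the CTC frequency but
invisible to nucleus-triggered review. Manual review is slow and
operator-biased; this package implements the quantitative alternative:
segment every channel, measure every object, and classify by a conjunction
of threshold predicates (a *gate*). The default CTC gate is

    mean CD45 ≤ 5,  mean DNA > 45,  mean CK > 60,
    mean Marker1 ≤ 5,  mean Marker2 ≤ 5,
    16 ≤ size_CK ≤ 400 px,  DNA-overlay-CK > 0.2

Downstream, per-patient counts are dichotomized at the ROC point minimizing
|sensitivity − specificity| (survival classes from the Kaplan-Meier median
overall survival), compared by Kaplan-Meier/log-rank, and modelled with Cox
proportional hazards including a **gamma shared frailty** per dataset,

    h_i(t) = z_g · λ0(t) · exp(x_i'β),   z_g ~ Gamma(1/θ, θ),  E z = 1,

with shifted-log covariate transforms (counts: ln(0.0001 + count/1000);
LDH/ALP: ln(0.001 + U/L/100)), forward stepwise selection
(p_in = 0.05, p_out = 0.10), and model comparison by Uno's IPCW C-index at
τ = 24 months with a 1000-replicate patient bootstrap. The Cox/frailty
machinery is implemented here (Efron ties, penalized-likelihood frailty with
profile marginal likelihood over θ); KM/log-rank use lifelines and Uno's C
uses scikit-survival. Because no clinical archive ships with the package, a
first-class simulator generates ground-truthed cartridges (planted cells,
vesicles, leukocytes, debris; Gaussian PSF; Poisson + Gaussian CCD noise)
and cohorts (correlated negative-binomial counts, lognormal plasma markers,
proportional-hazards survival with per-dataset frailty and right censoring),
so every stage is validated against a known truth. See `docs/methods.md`.

## Worked example

Simulate a ground-truthed cartridge and enumerate it:

```
$ ctcev simulate-images --out cart.tiff --truth-out truth.csv \
        --frames 8 --n-ctc 4 --n-tdev 60 --seed 7
wrote 8 frames to cart.tiff (144 planted objects)
$ ctcev enumerate --stack cart.tiff --out counts.csv
144 objects -> 4 CTC, 60 tdEV
```

144 segmented objects (the planted cells, vesicles, leukocytes, bare nuclei
and debris) funnel down to exactly the 4 planted CTCs and 60 planted tdEVs —
the other 80 objects fail the gates, as they should.

The full demonstration — two simulated datasets with a shared frailty, a
prognostic tdEV signal, CTC counts correlated ~0.8 with tdEV, and a null
ccCK18 —

```
$ ctcev run-all --outdir demo --seed 1
```

writes enumeration tables, descriptive statistics, ROC cut-offs (per dataset
for the plasma markers), KM curves with log-rank tests, univariable and
stepwise Cox reports, the C-index comparison, and a manifest. With seed 1 it
prints, among else: KM median overall survival 10.9 months in the
unfavorable tdEV group versus 27.9 in the favorable; stepwise selects
`tdev`, `albumin`, `ldh`, `hemoglobin` (ccCK18 and the collinear CTC count
are not retained); and Uno's C at 24 months is 0.690 for the tdEV model
versus 0.630 for the clinical-only model (Δ = 0.059) — the qualitative
pattern that makes tdEV counts a useful prognostic marker in this design.

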