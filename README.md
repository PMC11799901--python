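# sctqa

Patient-specific quality assurance (PSQA) tooling for synthetic CT (sCT) in
MR-only brain radiotherapy.

In an MR-only workflow no planning CT exists, so a patient's AI-generated
sCT cannot be validated against ground truth. One proposed remedy is to QA
the clinical sCT against sCTs from *other* generators and flag patients
whose dose recalculation disagrees. `sctqa` implements the full analysis
chain behind that idea and exercises it end-to-end on synthetic head
phantoms with plantable sCT failure modes, so every stage has a known
ground truth:

* **Phantom cohorts** — paired CT/sCT digital heads (skull, brain, air
  sinus, PTV) with planted error modes: faithful + noise, systematic
  soft-tissue density bias, sinus misprediction, metal-implant artifact
  (a true QA failure), and bulk-density class assignment calibrated to a
  target dose error.
* **Toy dose engine** — HU → relative density calibration, exact Siddon
  radiological path lengths, exponentially attenuated divergent beams with
  penumbra and inverse-square falloff, and the monitor-units-unchanged
  recalculation contract (normalisation fixed on the CT, reused on every
  sCT).
* **Metrics** — mean voxel dose error per structure
  (ME = mean(D_eval − D_ref), in Gy and % of prescription), DVH deltas
  ΔDx = (Dx_eval − Dx_ref)/D_pres for Dx ∈ {D2%, D95%, D98%, Dmean}, and a
  3D *local* gamma analysis (1%/1 mm, 20% low-dose threshold) with an
  exhaustive brute-force oracle for validation.
* **Classification** — inclusive tolerance limits (±1% point metrics,
  ≥90% gamma pass rate), the TP/FN/FP/TN ledger per QA generator against
  the CT verdicts, and sensitivity = TP/(TP+FN).
* **Positioning** — DRR generation (Siddon reuse), simulated orthogonal kV
  pairs at planted couch poses, bone-driven 2D/2D rigid registration by
  normalised cross-correlation, 3D rigid registration, and the CT-vs-sCT
  couch-correction difference after subtracting the static sCT/CT offset.
* **Pipeline + CLI** — `sctqa run` replays the whole study (cohort → doses
  → metrics → verdicts → sensitivity matrix → positioning), byte-identical
  per seed.

Structures can also come from real data: DICOM CT series, RTDOSE and
RTSTRUCT readers are included (brain/skull may be generated by HU
thresholding: brain [−100, 100] HU, skull ≥ 100 HU, inside the body).

## Worked example

An eight-patient demo cohort (one metal-artifact patient, one bulk-density
patient, the rest faithful), QA'd against the ground-truth CT and one
emulated faithful generator:

```bash
cat > study.yaml <<EOF
n_patients: 8
grid_shape: [64, 64, 64]
spacing_mm: [3.0, 3.0, 3.0]
n_metal: 1
n_bulk: 1
references: [CT, sCT_QA_AI_1]
EOF
sctqa run --config study.yaml --seed 7 --outdir out/
```

prints (about 20 s on one core):

```
INFO sctqa: patient 2 (METAL_ARTIFACT)
INFO sctqa: patient 2 refused by sCT_QA_AI_1 (artifact auto-rejection)
...
  reference         metric  tp  fn  fp  tn  n  sensitivity  specificity
sCT_QA_AI_1         ME_PTV   6   0   1   0  7          1.0          0.0
sCT_QA_AI_1   DeltaD2%_PTV   6   0   0   1  7          1.0          1.0
sCT_QA_AI_1  DeltaD95%_PTV   7   0   0   0  7          1.0          NaN
sCT_QA_AI_1  DeltaD98%_PTV   7   0   0   0  7          1.0          NaN
sCT_QA_AI_1 DeltaDmean_PTV   6   0   1   0  7          1.0          0.0
sCT_QA_AI_1  GammaPassRate   7   0   0   0  7          1.0          NaN
```

Reading this: the metal-artifact patient was refused by the emulated QA
generator (as its commercial counterpart does for MR artifacts) and is
excluded from the counts, leaving n = 7. The faithful QA generator accepts
every remaining patient, so its sensitivity is 1.0 for every metric. The
bulk-density patient sits right at its calibrated −1% mean-PTV-dose error,
so against the CT it flips between accept and reject depending on the
metric — visible as single tn/fp entries — exactly the borderline behaviour
a bulk-density generator produces in practice. Specificity is reported but
is NaN wherever no true rejection exists; with faithful generators true
negatives are rare, which is why sensitivity is the headline number.

`out/` holds the per-patient metric table, verdicts, the sensitivity
matrix, boxplot summaries with patient-tagged outliers and Wilcoxon
p-values, the positioning table, the cohort ground truth, and `study.json`
with the seed and tolerances. Other subcommands (`simulate`, `dose`,
`metrics`, `classify`, `position`) expose the individual stages on files.

## Scope

The dose engine is deliberately minimal (primary attenuation only) — any
deterministic, density-sensitive engine exercises the QA metrics, and only
dose *differences* between recalculations are meaningful. The phantoms make
no claim of anatomical realism beyond what the metrics and the bone-driven
registration require. See `docs/methods.md` for models, parameter defaults,
design decisions, and limitations.
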