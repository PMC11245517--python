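# fairseg — fairness-aware hip/knee bony-anatomy segmentation

AI segmentation of hip and knee bony anatomy on plain radiographs drives
pre-operative planning and post-operative assessment in orthopedics, but a
model that segments one demographic group worse than another is a patient
safety problem: pelvic geometry differs by sex, bone density by race, and
joint-space width by age, and a model trained on an imbalanced cohort can
inherit those differences as systematic errors. `fairseg` is a desk-scale,
fully offline framework for *measuring* that kind of group bias in
segmentation models and for *testing* the standard data-level mitigation
strategies — built for methodologists who want the entire
generate→train→audit→test loop to run in minutes on one CPU, with no access
to clinical images.

It provides:

* a **phantom radiograph generator** — parametric 2-D hip/knee scenes
  (femur, tibia, patella, pelvis) with exact ground-truth masks, a cohort
  composition taken from a published hip/knee study (766 hip + 707 knee
  patients across sex × race × age cells), and a bias knob δ that lowers the
  bone contrast-to-noise ratio of one designated disadvantaged group;
* a **hybrid encoder–decoder segmenter** written in pure NumPy — a U-Net-style
  decoder over a four-layer residual encoder (3×3 kernels, stride 2, widths
  64→128→256→512, scalable by a width multiplier), with hand-derived
  backward passes verified against finite differences;
* **four training strategies**: baseline, balanced (undersampling),
  stratified batching, and group-specific models, with the published
  hyperparameters as defaults (Adam, lr 5·10⁻⁴, cross-entropy, 50 epochs,
  batch 16) and a desk profile for CPU-scale runs;
* **group-fairness metrics**: per-class IoU and Dice,

  ```
  IoU = |P ∩ A| / |P ∪ A|        Dice = 2|P ∩ A| / (|P| + |A|)
  ```

  aggregated per protected group g, and the skewed error ratio

  ```
  SER = max_g (1 − s_g) / min_g (1 − s_g)
  ```

  (1 = perfectly fair) together with the population SD of group error rates;
* **significance testing**: within-group bootstrap SER replicates and a
  one-sided Welch t-test of H₁: SER_baseline > SER_candidate at α = 0.05.

## Worked example

Fairness arithmetic on a published result row — per-group mean IoUs of 0.842
and 0.844 correspond to error rates 0.158/0.156:

```python
from fairseg import compute_ser, compute_group_sd
scores = {"white_caucasian": 0.842, "black_african_american": 0.844}
print("SER =", round(compute_ser(scores), 3), " SD =", round(compute_group_sd(scores), 3))
```

```
SER = 1.013  SD = 0.001
```

An end-to-end bias-injection experiment: a 240-patient knee phantom cohort,
70/30 imbalanced by race, with the minority race rendered at half contrast
(δ = 0.5); a 1/8-width model trained 5 epochs and audited on a
composition-balanced 40-image test set:

```python
from fairseg.experiment import run_bias_experiment
result = run_bias_experiment(seed=4, delta=0.5, strategies=("baseline", "balanced"))
for strategy in ("baseline", "balanced"):
    report = result.reports[strategy]
    levels = report.entries["iou"]["per_level"]
    print(f"{strategy:9s} IoU  white={levels['white_caucasian']:.3f} "
          f"black={levels['black_african_american']:.3f} "
          f"SER={report.ser('iou'):.3f}  SD={report.sd('iou'):.3f}")
```

```
baseline  IoU  white=0.816 black=0.786 SER=1.162  SD=0.015
balanced  IoU  white=0.677 black=0.669 SER=1.025  SD=0.004
```

The baseline model is measurably unfair (SER 1.16: the disadvantaged group's
error rate is 16% higher), and undersampling the majority group restores
near-parity (SER 1.03) at a cost in overall accuracy — the classic
fairness/performance trade-off.

The same workflow is available from the shell, driven by a YAML config (see
`configs/desk_knee_bias.yaml`):

```bash
fairseg generate --config configs/desk_knee_bias.yaml
fairseg train    --config configs/desk_knee_bias.yaml
fairseg audit    --config configs/desk_knee_bias.yaml
fairseg significance --config configs/desk_knee_bias.yaml
fairseg replicate-tables
```

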