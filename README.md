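# mrmcbe

**Multi-Reader Multi-Case Bounding-box Evaluation** for AI-assisted
fracture-detection reader studies.

Radiology reader trials of AI assistance ask: does showing radiologists an
AI's fracture boxes change — and improve — their calls? `mrmcbe` implements
the full evaluation pipeline for the two-round design used in such trials
(round 1 unaided, round 2 with the AI output visible, a standalone AI
reader, and a consensus bounding-box ground truth), for researchers running
or re-analysing MRMC detection studies:

- **Box matching**: a reader/AI box detects a ground-truth fracture when
  their overlap is ≥ 40% (threshold and normalisation configurable:
  ground-truth-area fraction, IoU, or min-area fraction). One-to-one
  optimal assignment — maximum matched pairs, then maximum total overlap.
- **Three scoring levels**: per fracture (exact localization), per image
  (any box on the image), per examination (any positive image).
- **Diagnostic metrics with intervals**: sensitivity, specificity, PPV,
  NPV, accuracy; exact Clopper-Pearson intervals for
  accuracy/sensitivity/specificity and Wilson score (Newcombe
  efficient-score) intervals for PPV/NPV.
- **Agreement & decision changes**: mean pairwise Cohen's kappa
  (inter-reader and reader-vs-AI), and a round-1 → round-2 change taxonomy
  (direction, correctness vs ground truth, alignment with the AI).
- **Failure analysis**: fractures and false-positive sites where a reader
  majority (default 5 of 7) contradicted the AI, categorised by who was
  right.
- **Synthetic study generator**: seeded, label-exact two-round studies
  with configurable reader/AI error profiles, so the whole pipeline is
  testable without any clinical data.

The core statistics, in the field's standard notation: with confusion
counts (TP, FP, TN, FN) at a level,

    Se = TP/(TP+FN)   Sp = TN/(TN+FP)   PPV = TP/(TP+FP)
    NPV = TN/(TN+FN)  Acc = (TP+TN)/N

Clopper-Pearson bounds are the beta quantiles
`B(α/2; k, n−k+1)` and `B(1−α/2; k+1, n−k)`; the Wilson interval inverts
the score test `(p̂−p)/√(p(1−p)/n) = ±z`. Cohen's kappa is
`κ = (p_o − p_e)/(1 − p_e)` with `p_e` from the marginal products, averaged
over all reader pairs.

## Worked example

```python
from mrmcbe import generate_study, run_pipeline, clopper_pearson

ds = generate_study(seed=1)          # 107 exams, ~336 images, 7 readers + AI
bundle = run_pipeline(ds)
print(bundle.metric_tables["examination"])
```

```
                avg_radiologist  avg_radiologist_ai  delta_assisted    ai  delta_ai_vs_baseline  delta_ai_vs_assisted
True positive              56.4                54.7            -1.7  56.0                  -0.4                   1.3
False positive             18.1                20.7             2.6  21.0                   2.9                   0.3
True negative              29.9                27.3            -2.6  27.0                  -2.9                  -0.3
False negative              2.6                 4.3             1.7   3.0                   0.4                  -1.3
PPV                        75.7                72.5            -3.1  72.7                  -2.9                   0.2
NPV                        92.1                86.4            -5.6  90.0                  -2.1                   3.6
Sensitivity                95.6                92.7            -2.9  94.9                  -0.7                   2.2
Specificity                62.2                56.8            -5.4  56.3                  -6.0                  -0.6
Accuracy                   80.6                76.6            -4.0  77.6                  -3.1                   0.9
```

Columns are the averaged unaided readers, the averaged AI-assisted readers,
their delta, the standalone AI, and the AI's deltas against both reader
conditions; counts sum to the 107 examinations, percentages are rounded
half-up to one decimal with deltas computed before rounding. Agreement
rises toward the AI in round 2, as expected when readers adopt some of the
AI's calls:

```python
print(bundle.kappa_table.round(3))
```

```
             inter_reader_r1  inter_reader_r2  readers_vs_ai_r1  readers_vs_ai_r2
level
examination            0.411            0.413             0.337             0.542
image                  0.559            0.542             0.539             0.663
fracture               0.444            0.438             0.363             0.587
```

Interval arithmetic on plain counts:

```python
ci = clopper_pearson(80, 107)        # 80 correct of 107 examinations
print(f"[{100*ci.lower:.1f}%, {100*ci.upper:.1f}%]")   # -> [65.4%, 82.7%]
```

The same pipeline is available from the shell:

```bash
mrmcbe simulate --seed 1 --out study.json
mrmcbe analyze --study study.json --out report/        # CSV + JSON + Markdown
mrmcbe metrics --counts 56,18,24,9                     # one confusion quadruple
mrmcbe sweep --study study.json --thresholds 0.2,0.4,0.6
```

Study files are plain JSON (schema in `src/mrmcbe/schemas/study.schema.json`)
or a CSV bundle (`images.csv`, `examinations.csv`, `annotations.csv`);
round-trips are lossless.

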