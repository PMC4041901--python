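# t1topo — contrast-free myocarditis tissue characterization on native T1-maps

Acute myocarditis is usually characterized on cardiovascular MR with
T2-weighted (T2W) edema imaging and late gadolinium enhancement (LGE), which
requires contrast injection. Native T1-mapping measures the tissue T1
relaxation time (ms) directly, without contrast, and edema/inflammation
raises T1. `t1topo` implements the quantitative analysis chain that makes
T1-mapping usable as a stand-alone tissue-characterization method, and a
calibrated digital cardiac phantom to exercise it end to end:

- **Detection criteria** on co-registered short-axis stacks:
  - native T1: pixels with **T1 ≥ 990 ms**;
  - dark-blood T2W: myocardial/skeletal-muscle SI ratio ≥ 2.0, or
    SI ≥ remote mean + 2 SD;
  - LGE: SI ≥ remote mean + 2 SD of remote myocardium;
  all restricted to contiguous areas ≥ **40 mm²** (8-connected, in-plane) to
  suppress noise, with an algorithmic remote-reference selection and
  per-segment quality-control exclusion.
- **Incremental-threshold topography**: applying a rising ladder of T1
  thresholds (990 → 1200 ms) yields nested lesion maps whose hot core
  reveals the non-ischemic (subepicardial/midwall, lateral/inferior)
  injury pattern; components are classified by transmural layer terciles
  and AHA wall.
- **Quantification**: per-segment percentage of abnormal myocardium averaged
  per subject, mean myocardial T1, global T2 SI ratio, AHA 16-segment model.
- **Diagnostics**: sensitivity/specificity/accuracy/PPV/NPV for single and
  any-k-of-n combined criteria, rank-based ROC AUC, DeLong comparison of
  paired AUCs, McNemar and Cochran's Q tests.
- **Phantom** (`t1topo.phantom`): synthetic multiparametric cohorts
  (default 50 controls + 41/12/7 patients in Groups I edema+/LGE+,
  II edema−/LGE+, III edema−/LGE−) with pixel-level ground truth,
  calibrated so controls sit at T1 = 946 ± 23 ms and the T1 criterion
  operates at ~90% patient-level sensitivity.

## Worked example

```python
from t1topo.pipeline import RunConfig, run_all

bundle = run_all(RunConfig(master_seed=1))
t2 = bundle["table2"].set_index("criterion")
print(t2.loc["t1", ["sensitivity", "specificity", "accuracy"]].round(1))
print(bundle["roc"].round(3))
```

prints (seed 1):

```
sensitivity    91.7
specificity    78.0
accuracy       85.5
Name: t1, dtype: float64
  criterion    auc
0        t1  0.847
1       t2w  0.599
2       lge  0.942
```

i.e. on this synthetic cohort the T1 ≥ 990 ms criterion detects 55 of the 60
patients (91.7% sensitivity, against the generator's 90% calibration target)
at 78% specificity, and the per-method AUCs order LGE ≳ T1 > T2W. The same
run yields the segmental extent table: the median patient extent of injury
is ~23% by T1 versus ~7% by LGE and ~0% by T2W — T1-mapping uncovers
involvement the comparators miss.

The numbered drivers under `analysis/` tell the full story and write their
tables under `results/`:

```bash
python analysis/01_simulate_cohort.py   # cohort + calibration report
python analysis/02_detect_lesions.py    # criterion decisions per subject
python analysis/03_quantify_extent.py   # tissue-characteristics summary
python analysis/04_topography.py        # incremental-threshold panels
python analysis/05_diagnostics.py       # diagnostic-performance tables
```

A thin CLI mirrors the same steps (`t1topo generate | detect | topo | run`).

## Layout

```
src/t1topo/     model, phantom, detection, topography, quantify,
                diagnostics, pipeline, cli
analysis/       numbered narrative drivers
tests/          pytest suite (unit, property and end-to-end checks)
docs/methods.md model assumptions, calibration and limitations
```
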