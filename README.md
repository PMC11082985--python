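# indexroc

Unified evaluation of quantitative and qualitative diagnostic bioassays:
ROC and predictive-value curves with integrated cut-off distributions,
Youden/PSI index curves, unified optimal cut-off determination, and an
inverse-lookup bridge that places a visually read test on the quantitative
concentration scale.

## Who this is for

Clinical chemists, epidemiologists and biostatisticians evaluating a
continuous biomarker test (e.g. a urinary tumour-marker read by a
photometric point-of-care reader) against a gold standard, who need more
than a traditional ROC curve:

- the cut-off behind every curve point, not just the (Se, Sp) trade-off;
- predictive values (PPV/NPV), which — unlike Se/Sp — depend on disease
  prevalence and drive actual clinical decisions;
- a *single* threshold that is simultaneously optimal for the
  sensitivity/specificity profile and the predictive-value profile;
- a quantitative anchor for a qualitative visual version of the same assay.

## The statistics

Dichotomising a marker at cut-off `c` (positive iff value ≥ `c`) gives
confusion counts and from them `Se`, `Sp`, `PPV`, `NPV`. Two summary
indices condense each pair:

    J(c)   = Se(c) + Sp(c) − 1        (Youden index, SS family)
    PSI(c) = PPV(c) + NPV(c) − 1      (Predictive Summary Index, PV family)

Their reciprocals have a person interpretation: `1/J` is the number of
diseased persons to examine to correctly detect one; `1/PSI` the number of
persons to examine to correctly predict one diagnosis.

The package builds, over a preset concentration grid (default
`5, 7.5, 10, 30, 50, 90, 110, 250, 300` µg/L, detection floor 0.5 µg/L):

- **CDA curves** — each metric against the cut-off;
- **SS-ROC** `(1−Sp, Se)` and **PV-ROC** `(1−NPV, PPV)`, every point
  annotated with its cut-off (PV-ROC has no AUC and the object refuses to
  compute one);
- **index-ROC curves** — `J` vs `1−Sp`, `PSI` vs `1−NPV`;
- the **index cut-off diagram** — `J(c)` and `PSI(c)` on a common cut-off
  axis. The crossing of the two piecewise-linear curves (located by
  bracketing + Brent bisection to 1e−6 µg/L) is the **unified optimal
  cut-off**; **AOX** areas (∫ max(index, 0) dc) summarise effectivity over
  full or partial cut-off ranges; reciprocal diagrams restate everything
  in persons;
- the **qualitative bridge** — inverse lookup of a visual test's observed
  (Se, Sp) or (PPV, NPV) on the reader's CDA curves yields its implied
  concentration cut-off, and the reader's diagnostic gain over the visual
  read-out in percentage points.

Empirical predictive values always satisfy the Bayes relation
`PPV = Se·p / (Se·p + (1−Sp)(1−p))` (and its NPV analogue) at the
cohort's prevalence `p`; `bayes_predictive_values` transports a profile to
any other prevalence.

See `docs/methods.md` for conventions (≥ positivity, undefined-value
handling, AUC anchors, interpolation and clipping rules) and limitations.

## Worked example

Simulate a study-sized cohort (91 diseased / 1152 disease-free, prevalence
0.073, log-normal marker mixture) and run the full pipeline:

```sh
$ indexroc simulate --seed 1 --out cohort.csv
wrote cohort.csv (prevalence 0.0732)

$ indexroc unified --input cohort.csv
{
  "cutoff_star_ug_per_L": 25.859290160373728,
  "index_star": 0.5662560130261372,
  "bracket_ug_per_L": [10.0, 30.0],
  "all_crossings": [[25.859290160373728, 0.5662560130261372]],
  "method": "crossing"
}

$ indexroc report --seed 1 --outdir bundle
$ cat bundle/report.txt
indexroc analysis report (config da2aa709396239fa)
==============================================
cohort: n=1243 (91 diseased / 1152 non-diseased), prevalence 0.073
grid (µg/L): 5, 7.5, 10, 30, 50, 90, 110, 250, 300
positivity: value >= threshold

SS-ROC AUC (grid trapezoid): 0.865
max SS-J index: 0.581
max PV-PSI index: 0.930
unified cut-off: crossing at 25.9 µg/L, index 0.566
AOX (SS-J, clipped at 0): 62.4 index·µg/L (mean level 0.211)
AOX (PV-PSI, clipped at 0): 252.0 index·µg/L (mean level 0.854)
```

Reading the numbers: on this synthetic cohort the J and PSI curves cross
at 25.9 µg/L with common index 0.566 — the single cut-off at which the
SS and PV summaries agree on their value; at that threshold roughly
`1/0.566 ≈ 1.8` persons must be examined per correct detection. The
bundle directory also contains the per-cutoff metric table, all curves as
tidy CSV, the six plot types (SVG), and JSON results, every file stamped
with the configuration hash for provenance.

The same computations are available as a library:

```python
from indexroc import (CohortSpec, ThresholdGrid, generate_cohort,
                      index_cutoff_diagram, unified_cutoff)

cohort = generate_cohort(CohortSpec(seed=1))
diagram = index_cutoff_diagram(cohort, ThresholdGrid.default())
print(unified_cutoff(diagram).to_dict())
```

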