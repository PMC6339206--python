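# danpmv

Hierarchical multi-criteria decision analysis combining DEMATEL-based ANP
influential weights with modified-VIKOR aspiration-gap scoring, for decision
problems whose factors influence one another — for example assessing and
improving quality of life with the WHOQOL-BREF indicator hierarchy (4
dimensions, 26 criteria).

The package is for analysts who collect two small surveys — expert pairwise
influence judgments on a 0–4 integer scale and respondent satisfaction
scores on a bounded Likert scale — and want, from them:

- the **total influence matrix** `T = N(I − N)⁻¹` per block, where
  `N = uA` is the panel-averaged direct-influence matrix scaled by
  `u = min(1/max row sum, 1/max column sum)`;
- the **influential network relation map (INRM)**: each factor at
  `(oᵢ + rᵢ, oᵢ − rᵢ)` (row/column sums of `T`), classified as a net cause
  (`oᵢ − rᵢ > 0`) or receiver, with arrows from the stronger to the weaker
  direction of each mutual influence;
- **influential weights**: the stationary distribution `π` of the
  row-normalised total influence, `π Tᵅ = π`, computed once at the dimension
  level and once inside each dimension, then composed into global criterion
  weights `w^g_c = w^l_D · w^l_{D_c}`;
- **aspiration gaps**: each score's distance to the aspiration level
  `f^aspired` (the top of the survey scale), rolled up with the weights into
  dimension and overall performance/gap and the mean group utility
  `S_k = Σⱼ w^g_j · r_kj`.

The hierarchical questionnaire design surveys dimensions and
within-dimension criteria separately, so a 4×26 hierarchy needs
`4·3 + 7·6 + 6·5 + 4·3 + 9·8 = 168` pairwise items instead of the classic
full-matrix `26·25 = 650`.

## Worked example

The bundled `xingshisi` fixture is a complete rural quality-of-life case:
the five panel-averaged influence matrices and a 26-criterion village
satisfaction survey on a 1–7 Likert scale with aspiration level 7.

```python
import danpmv

hierarchy, panels, survey = danpmv.load_case_fixture("xingshisi")
run = danpmv.run_hierarchical(panels, hierarchy)
print({d: round(w, 3) for d, w in run.weights.local_dimension_weights.items()})
# {'D1': 0.245, 'D2': 0.295, 'D3': 0.249, 'D4': 0.211}

report = danpmv.aggregate_report(run.weights, survey, hierarchy, dialect="raw")
village = report.alternatives[0]
print(round(village.overall_performance, 3), round(village.overall_gap, 3))
# 5.81 1.19
```

The psychological-state dimension (D2) carries the largest weight, 0.295.
Overall satisfaction is 5.810 of 7, leaving an aspiration gap of 1.190 —
driven mainly by physical capacity (D1, dimension gap 2.157), within which
work capacity shows the single largest criterion gap (7 − 2.333 = 4.667).
The INRM classifies D1 and D4 (environment) as net causes of the system and
D2, D3 as receivers, so improvement effort belongs at the causes, not at the
symptoms.

The same pipeline runs from the shell:

```sh
danpmv run --fixture xingshisi --out out/        # full report + INRM exports
danpmv item-count --fixture xingshisi            # 168 hierarchical vs 650 classic
danpmv simulate --fixture xingshisi --experts 10 --seed 1 --out panels/
```

or from your own files: a JSON/YAML hierarchy config plus labeled-CSV
matrices per block (see `src/danpmv/fixtures/xingshisi/` for the format).

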