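# afscreen

Modeled effectiveness of community screening for untreated atrial
fibrillation (AF) in the elderly.

AF is often silent, and untreated AF carries a high stroke risk that oral
anticoagulation largely removes. A community screening campaign (single
30-second ECG during a blood-pressure measurement, cardiologist
over-read) can surface untreated AF in people aged 65 and over — but is
finding those cases worth it? This package implements the analysis
pipeline that answers the question for a Japanese screening setting, for
epidemiologists and health-services researchers:

- **Markov cohort model** (`afscreen.markov`, `afscreen.microsim`): an
  annual-cycle three-state model (alive pre-stroke → post-stroke → dead)
  with age/sex-banded transition probabilities for three alive profiles
  (non-AF, DOAC-treated AF, untreated AF), producing discounted
  life-years and QALYs per strategy and their differences, plus an
  individual-level Monte-Carlo cross-check of the recursion.
- **Screening statistics** (`afscreen.screening`): detection rates with
  Clopper–Pearson intervals, number needed to screen (NNS), stratified
  2×2 comparisons with Fisher's exact test, Cohen's κ for the two ECG
  readers, CHADS₂ / CHA₂DS₂-VASc scoring, diagnostic accuracy.
- **National projection** (`afscreen.projection`): applies the detected
  prevalence of anticoagulation-eligible cases to an age×sex population
  table and converts identified cases into strokes prevented over a
  10-year treatment horizon via the model's absolute risk reduction.
- **Synthetic cohort** (`afscreen.cohort`): a seeded generator with the
  campaign's marginal structure, and a deterministic 1607-record fixture
  whose stratified counts match the published campaign tables exactly.

## Model

For a cohort entering at age $a_0$ in alive profile $s \in \{\mathrm{nAF},
\mathrm{tAF}, \mathrm{utAF}\}$, each annual cycle $k$ (age $a = a_0 + k$)
applies, in order: death from any cause with $p^{s}_{\text{death}}(a)$;
stroke among survivors with $(1-p^{s}_{\text{death}}(a))\,
p^{s}_{\text{stroke}}(a)$; acute case fatality $f(a)$ splitting incident
strokes into acute deaths and post-stroke entrants; post-stroke death with
$p_{e_1 e_2}(a)$. Utility weights are 1 for alive pre-stroke,
$u_{\text{post}}(a)$ (0.68 below 75, 0.56 at 75+) post-stroke, and
$u_{\text{post}}(a) - 0.14 \times 0.25$ in the stroke cycle. Totals are

$$\mathrm{QALY} = \sum_k (1+r)^{-k} \sum_{\text{states}} w\,\pi_k,$$

with $r = 2\%$, half-cycle credit for within-cycle deaths, and the
terminal 100+ band forcing death. The accrual and discount-base
conventions are not stated in the source tables, so
`calibrate_conventions` fixes the pair once against a single published
life-expectancy anchor cell and everything else is validated with the
pair frozen.

## Worked example

```python
import afscreen as af

tables = {sex: af.default_transitions(sex) for sex in ("men", "women")}
qol = af.default_qol()
config = af.calibrate_conventions(tables["men"], qol)

r = af.effectiveness_difference("men", 65, tables["men"], qol, config)
print(f"{r.qalys_treated:.3f} {r.qalys_untreated:.3f} {r.qalys_gained:.3f}")
```

prints `13.137 12.248 0.889`: a 65-year-old man with screen-detected AF
can expect 13.137 discounted QALYs if anticoagulated and 12.248 if left
untreated — a gain of 0.889 QALYs per treated case. The
`examples/` scripts walk through each capability (QALY table, screening
summary, national projection, synthetic-cohort generation) and print what
every number means; `afscreen --help` exposes the same workflow as a thin
CLI (`qaly`, `sensitivity`, `screen-stats`, `project`, `simulate`).

Reproducing the published national totals (~190 k untreated AF identified,
~8 k strokes prevented) additionally needs the external 2019 Vital
Statistics population table; `examples/national_projection.py` shows the
computation on a synthetic population of similar size.

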