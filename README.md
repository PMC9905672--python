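# vhi — Vascular Health Index toolkit

`vhi` computes a composite, equal-weighted, percent-of-ideal **Vascular
Health Index (VHI)** for microvascular networks, built for studies of
metabolic disease in lean (LZR) and obese (OZR) Zucker rats and for anyone
who needs to reduce pressure-myography and histology readouts to a single
interpretable health score per animal.

The index combines three measured components per vascular bed (skeletal
muscle gracilis arteriole or middle cerebral artery):

1. **Endothelium-dependent dilation** — the upper bound `max` of the logistic
   acetylcholine concentration–response fit
   `y = min + (max − min) / (1 + 10^(logEC50 − x))`, with `x = log10[ACh]`;
2. **Microvessel density (MVD)** — vessels/mm² of tissue cross-section;
3. **Wall stiffness β** — the slope of `ln σ` vs `ε` from the passive
   (Ca²⁺-free) circumferential stress–strain relation, where
   `σ = P·ID/(2·WT)` and `ε = (ID − ID₀)/ID₀`.

Each component is scored against the age- and bed-matched mean of healthy
LZR controls: `100·m/s` for components that fall with disease, and
`100 + (100 − 100·m/s)` for stiffness, which rises. The VHI is the
unweighted mean of the three scores ("percentage" mode); an optional
"percentile" mode rank-normalizes each component within the pooled
population first — so β's large dynamic range cannot dominate — and anchors
the LZR cohort mean at exactly 100.

The package also ships the validity statistics used to qualify the index
(Pearson criterion correlations with plasma insulin/TNF-α, one-way ANOVA
with Newman–Keuls post hoc comparisons, an LZR > OZR > OZR+L-NAME
discriminant ordering check) and a synthetic-cohort simulator calibrated to
the published group×age means ± SE, so the full pipeline runs with no animal
data.

## Worked example

`examples/` holds one short script per capability. `03_score_cohort.py`
generates table-calibrated 17-week cohorts (20 animals each), derives the
health standards from the LZR animals, and scores everyone:

```
standards (17 wk skeletal, n=20 LZR): ACh 141.7 um, MVD 865 /mm^2, beta 3.07

percentage mode:
  LZR       VHI =  100.0 +/-  2.1 (SE)
  OZR+CAP   VHI =   75.0 +/-  2.3 (SE)
  OZR       VHI =   63.3 +/-  6.7 (SE)

percentile mode:
  LZR       VHI =  100.0 +/-  3.7 (SE)
  OZR+CAP   VHI =   50.1 +/-  3.7 (SE)
  OZR       VHI =   45.7 +/-  7.7 (SE)
```

Read: 100 = ideal age-matched vascular health. Untreated OZR at 17 weeks
retain about two-thirds of ideal health in percentage mode; chronic
captopril closes part of that deficit. Percentile mode spreads the same
animals by rank, which is harsher on any deviation from the healthy pool but
immune to one component dominating.

The same flow is available from the shell:

```sh
vhi simulate --groups LZR,OZR,OZR+CAP --ages 17 --bed skeletal --seed 1 --outdir study/
vhi fit-reactivity study/dose_response.csv --out study/reactivity_fits.csv
vhi fit-mechanics  study/mechanics.csv     --out study/mechanics_fits.csv
vhi score study/animals.csv --out study/scores.csv
vhi summarize study/scores.csv --out study/summary.csv
vhi run --outdir study_full --seed 1     # the whole chain in one command
```

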