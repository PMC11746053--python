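# cqtriage

Molecular triage of cervical cytology from RT-qPCR quantification cycles.

Cervical screening rests on cytology (variable sensitivity for high-grade
squamous intraepithelial lesions and worse) and HPV testing (moderate
specificity because most infections are transient). A small panel of
cellular mRNAs whose expression shifts with lesion severity offers a third,
objective readout. `cqtriage` implements the full analysis pipeline for
such a panel: two mRNAs upregulated with severity (*CDKN2A*, *TOP2A*), six
downregulated (*MAL*, *CRNN*, *CRISP3*, *SPINK5*, *ECM1*, *TMPRSS4*), and
two housekeeping adequacy controls (*PGK1* for RNA, *HMBS* for DNA).

## The method

Instead of normalizing every marker to a housekeeping gene, two oppositely
deregulated mRNAs X and Y are combined into a pair feature

```
ΔCq(X, Y) = Cq(Y) − Cq(X) = log2( C(X) / C(Y) )
```

so the two expression shifts add and no housekeeping channel is consumed.
A linear classifier over n such pairs emits the decision function

```
DF = w0 + Σᵢ wᵢ · ΔCqᵢ
```

with DF > 0 calling an increased risk of ≥HSIL (HSIL or cervical cancer).
Weights come from essentially unpenalized logistic regression with
stratified K-fold cross-validation; the intercept doubles as the cutoff and
is re-tuned per diagnostic strategy (balanced, sensitivity-first,
specificity-first). Performance is reported as ROC AUC with DeLong
intervals and sensitivity/specificity with exact Clopper–Pearson intervals.
Technical error is propagated by enumerating every replicate combination
(5 mRNAs × 5 replicates → 3125 DF values per specimen) and summarizing the
DF coefficient of variation. A 0–100 "aberrancy" heat map (min → 0, median
→ 50, max → 100, falling markers inverted) summarizes all biomarkers with
discrepant (false-negative / false-positive) specimens grouped first.

Because no per-sample Cq data are publicly deposited, the package ships a
synthetic cohort generator emulating the study design (61 NILM / 28 LSIL /
42 HSIL / 36 CC; Gaussian Cq noise; HPV load and lactobacilli fraction
coupled through a latent severity score) so every stage is testable end to
end, plus a bundled nine-specimen reference table from the prototype
two-tube assay for worked-example checks.

## Worked example

`python analysis/06_worked_example.py` scores the bundled nine-specimen
reference table. Ordinary least squares on the published DF values
recovers the 4-pair classifier (max residual 0.0014, i.e. the table is
consistent with a single affine decision function) and reproduces every
published value and call:

```
sample_id diagnosis      df  published_df           call
   NILM-1      NILM -0.1795       -0.1797       low_risk
   LSIL-2      LSIL -0.6358       -0.6364       low_risk
   HSIL-1      HSIL  0.5128        0.5122 increased_risk
     HeLa   UNKNOWN  3.8164        3.8160 increased_risk
leave-one-out DF prediction for HSIL-2: 0.8916 (published 0.8935)
```

Negative DF ⇒ low risk of ≥HSIL; the HeLa cancer cell line scores far
above the cutoff because its three downregulated epithelial mRNAs do not
amplify at all (Cq capped at 40).

The numbered scripts under `analysis/` run the full synthetic study —
`01` simulate, `02` screen all 36 pairs, `03` train/evaluate classifiers,
`04` replicate error, `05` heat map — writing tables under `results/`.
The equivalent `cqtriage` CLI (`simulate`, `screen-pairs`, `train`,
`score`, `heatmap`) works on any wide/long Cq CSV.

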