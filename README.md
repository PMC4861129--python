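# metsig

Integrative metabolomic–transcriptomic gene-signature analysis for tissue
cohorts, built around the workflow used to derive prognostic metabolic gene
signatures in bladder cancer: targeted LC-MS metabolite profiles are tested
for tumor-vs-benign differences, mapped to the enzymes and genes of the
affected pathways, intersected with transcriptome differentials into an
integrated gene signature, scored per specimen, and stratified against
survival — with a final combinatorial refinement of the signature across
independent cohorts.

The package is aimed at computational biologists who want each of those
stages as a tested, reusable library function (plus a CLI), together with a
synthetic-study generator that produces every input with known ground
truth, so the whole pipeline can be validated without access to any
clinical cohort.

## The analysis

1. **Internal-standard normalization.** Raw peak areas are acquired under
   several chromatography methods, each spiked with internal standards
   (e.g. zeatin, tryptophan-¹⁵N₂). For sample *s* and method *m*, every
   metabolite of that method is divided by the median standard abundance
   of (*m*, *s*), then log2-transformed and per-metabolite median-centered.
2. **Differential metabolites.** Two-sample t-tests per metabolite with
   Benjamini–Hochberg adjustment; metabolites are called at FDR q ≤ 0.15.
3. **Pathway mapping and overrepresentation.** Differential metabolites
   map to gene symbols (KEGG-style enzyme assignments); gene sets are
   tested by the upper-tail hypergeometric probability
   P(X ≥ k) with parameters (N, K, n, k) and BH q-values.
4. **Integrated signature.** Transcripts differential between tumor and
   normal (|log2 FC| ≥ 1 and p < 0.05) are intersected with the mapped
   genes; each signature gene keeps its transcript log2 fold-change and is
   *induced* (FC > 0) or *repressed* (FC < 0).
5. **Sum z-score activity.** Per specimen,
   S_s = Σ_{g induced} z_{g,s} − Σ_{g repressed} z_{g,s}, with z computed
   gene-wise across the cohort (sample sd).
6. **Survival stratification.** Specimens ranked by S are split at
   quantile breakdowns (default bottom 25% vs top 75%) and compared by the
   log-rank test; a univariate Cox fit (Newton–Raphson, Breslow ties)
   handles the continuous score.
7. **Refinement.** Genes prognostic in the same direction in every cohort
   (one-gene signatures scanned over a threshold grid) enter a
   deterministic combinatorial subset search; the first subset (largest
   first) significant with a concordant direction in all cohorts at the
   25/75 breakdown is the focused signature.

The published 30-gene integrated signature and its focused 6-gene subset
(CHIT1, DNMT1, GPD1, PLA2G4A, TARSL2, SETD7) ship as fixtures
(`metsig.load_signature_fixture`), ready to score any expression matrix.

## Worked example

`analysis/` contains numbered scripts that run the whole story on one
synthetic study (145 metabolites / 31 planted differential, 46 tumor vs 14
benign, four methods; 377-specimen expression cohort with a planted 6-gene
prognostic signature, β = 1.5, 30% censoring, seed 42), writing tables to
`results/`:

```bash
python analysis/01_simulate_study.py
python analysis/02_metabolite_differential.py
...
python analysis/06_refine_signature.py
```

Output of steps 02 and 05 (what the code actually prints):

```
tested 145 of 145 metabolites (4 methods, internal standards removed)
differential at FDR 15%: 42
planted: 31; recovered: 31; false calls: 11
```

All 31 planted metabolites are recovered; the 11 extra calls are the price
of the permissive 15% FDR on 114 null metabolites.

```
93-gene signature scored on 377 specimens
25/75 split: 95 low vs 282 high
log-rank: chi2=9.328, p=0.00226, direction=worse survival for high scores
Cox (continuous score): beta=0.024 (se 0.006), Wald p=0.000104, score p=0.000105
```

The 25/75 split of 377 scored specimens yields groups of 95 and 282, and
high signature activity carries significantly worse survival — the planted
direction. Step 06 then recovers exactly the six planted prognostic genes
as the refined subset across three independent cohorts.

The same pipeline is available as a CLI (`metsig simulate`, `metsig
run-all --config run.yaml`, and one subcommand per stage); `metsig score
--fixture table2_30gene --expression expr.tsv --out scores.tsv` applies the
published signature to your own cohort.

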