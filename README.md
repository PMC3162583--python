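# ginipipe

Analysis pipeline for hunting an X-linked prostate-cancer predisposition
gene in sibling-pair families, built around four statistical stages and a
synthetic-data generator that emulates the study design end to end.

The scientific setting: hereditary prostate cancer families linked to the
*HPCX1* locus (Xq27–q28) each contribute one affected man and one healthy
brother. Because males are hemizygous for X, a truncating germline mutation
cannot hide behind a wild-type allele, so nonsense-bearing transcripts can
be exposed by pharmacologically blocking nonsense-mediated mRNA decay (NMD)
in lymphoblastoid cells and comparing each sample with itself — the GINI
strategy (Gene Identification by NMD Inhibition). Around that screen the
pipeline adds a rank-based miRNA profiling statistic, variant-driven
miRNA-target scoring, and carrier-frequency association tests.

## The four stages

**1. NMD differential expression** (`ginipipe.nmd`). Each individual's
two-color array (treated channel *r*, untreated *g*) yields per-probe
background-adjusted log-ratios `y = ln(r/g)`, quantile-normalized between
arrays. For each gene in the region of interest, the model

```
y_fi = mu + beta * affected_fi + u_f + e_fi ,   u_f ~ N(0, s2_fam),  e_fi ~ N(0, s2_res)
```

is fitted by REML (profiled over the variance ratio), and a gene is called
when `beta > 0` and the t-test on `n_families − 1` degrees of freedom gives
`p < 0.025`. Stress-response genes — upregulated by the NMD-blocking drug in
*every* sample — are excluded by list; a fold-change threshold and a
cytogenetic-band whitelist (default Xq27/Xq28) are configurable.

**2. Within-family directional Kendall-tau distance** (`ginipipe.famtau`).
The dissimilarity between two expression profiles over M miRNAs is the
Kendall-tau distance `d = (1 − tau)/2`; each feature pair's discordance
mass is split equally between its two members, giving per-miRNA
contributions `c_m` with `sum_m c_m = d` exactly. Within each family the
mean contribution over all (patient, healthy) pairs is signed by which
status group has the higher average rank; summing the signed components
over families gives the overall directional distance `D_m`. One-sided
p-values (up- or downregulated in patients) come from permuting affection
labels within families only — Monte-Carlo with an add-one estimator, or
exact enumeration on small designs. Individuals are clustered on the
pairwise tau distances with Ward's method (Lance–Williams on raw
distances).

**3. Variant-induced target-site deltas** (`ginipipe.target_delta`).
Mature miRNAs are aligned antiparallel against windows centred on each
sequence variant using Smith–Waterman local alignment with Watson–Crick
(+5) and G:U wobble (+2) pairs, −3 mismatches, affine gaps (−9/−4), and
doubled weights in the seed (miRNA positions 2–8). The score difference
`delta = wt − mut` is positive when a substitution destroys a site and
negative when it creates one; the top 5% of deltas are flagged.

**4. Carrier-frequency association** (`ginipipe.association`). 2×2 carrier
tables give odds ratios with Woolf (logit) 95% confidence intervals
`exp(ln OR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d))`, chi-square p-values,
control-group pooling, exact binomial carrier-frequency intervals, and a
female-genotype Hardy–Weinberg chi-square for X-linked markers.

`ginipipe.simulate` generates every input with planted ground truth;
`ginipipe.pipeline` runs seeded end-to-end configurations.

## Worked example

```
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_nmd_differential_expression.py
python analysis/03_mirna_family_distance.py --seed 0
python analysis/04_variant_target_delta.py
python analysis/05_carrier_association.py
```

prints (abridged):

```
selected 6 genes at alpha=0.025: 5/5 planted NMD genes recovered, 0 stress genes leaked, 1 false positives
top upregulated (overall distance, p_up):
  mir-003  D=+0.0069  p_up=0.0010  truth=up
  mir-001  D=+0.0064  p_up=0.0010  truth=up
  mir-002  D=+0.0057  p_up=0.0010  truth=up
threshold at top 5%: delta >= 12.05; 16 combinations flagged
planted site-disrupting combinations flagged: 10/10
unselected_pc 13/757 (1.72%) vs donors_bph (14/1896): OR 2.35 (1.10-5.02), p = 0.023
hpc_probands 4/163 (2.45%) vs donors_bph (14/1896): OR 3.38 (1.10-10.40), p = 0.024
```

Reading the output: the GINI stage recovers all five planted
NMD-responsive genes while the drug-stress genes are excluded by design;
the directional tau statistic puts the three up-shifted miRNAs at the top
of the distance ranking with the smallest attainable permutation p-value
(B = 2000, add-one estimator: 1/2001); all ten planted site-disrupting
variants land in the top-5% delta selection; and the carrier tables give an
odds ratio of 2.35 (95% CI 1.10–5.02) for unselected prostate cancer and
3.38 (1.10–10.40) for hereditary prostate cancer against the pooled
blood-donor/BPH controls. Stage tables land in `results/`.

## Layout

```
src/ginipipe/     library: simulate, nmd, famtau, target_delta, association,
                  io, pipeline, datasets
analysis/         numbered narrative drivers for the five stages
tests/            pytest suite with independent brute-force oracles
scripts/          acceptance.py (see above)
docs/methods.md   modelling assumptions, parameter choices, limitations
```
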