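# ssfuse

Disulfide (S-S) bond topology determination by Dempster-Shafer fusion of
heterogeneous bond-level evidence.

Disulfide bridges cross-link pairs of cysteines and shape protein folding,
stability and regulation. No single determination technique is reliable
across molecules: tandem-MS inference fails when precursor ions fragment
poorly, sequence-based predictors (SVM classifiers on local environments,
cysteine-separation-profile lookup) misfire when sequence similarity does not
track structure, and their outputs routinely conflict. `ssfuse` treats each
method as an evidence source over the frame of candidate bonds and fuses them
with Dempster-Shafer theory, which handles concurring *and* conflicting
evidence without distributional assumptions. It is aimed at proteomics
researchers who have per-method bond scores (or raw spectra and sequences)
and want a single, conflict-aware connectivity call.

## The model

For a protein with cysteines `C_1..C_n`, each method `k` reports a set
`D_k = {(C_i, C_j, sigma_k)}` of candidate bonds with confidence
`sigma in [0, 1]`. The frame of discernment `theta` is the set of candidate
bonds (by default the union of all reported bonds). Each method's scores are
turned into a basic belief assignment `m : 2^theta -> [0, 1]` over
*consistent* subsets (bond sets sharing no cysteine; inconsistent subsets
carry mass 0) via

```
m(j) = max( sum_i (2 sigma_i + gamma_i - 1) / k , 0 ),
gamma_i = -S/2k  if sigma_i = 0,   +S/4k  if sigma_i > 0     (S = sum_i sigma_i)
```

so extreme scores (0 or near 1) move subset mass much more than middling
ones. Raw masses are sum-normalised when they exceed 1; otherwise the deficit
becomes environment (ignorance) mass. Mass functions are then combined
n-arily under four rules — Dempster (conflict normalised out), Yager
(conflict enlarges ignorance), Campos (orthogonal sum de-rated by the weight
of conflict `log X = log 1/(1-k)`), and Shafer (per-source reliability
discounting by `alpha_i`, then averaging) — and per-bond beliefs are read off
as containment sums. A maximum-weight matching over per-bond scores yields
the globally consistent topology.

The constituent predictors are included: MS scoring (in-silico digestion,
12-ion-type fragment generation for disulfide-linked peptide pairs,
subset-sum search-space trimming, intensity-weighted match score VS, binomial
`pp` and Gaussian-abundance `pp2` significance scores), a 521-feature
window-encoded SVM contract with Platt calibration, and
cysteine-separation-profile matching with divergence-based beliefs
`sigma_CSP = (1 + log10(1 + D/10))^-2`. Reliability weights for the Shafer
rule are data-driven: heavy precursors (> 4000 Da) and weak matched abundance
(`pp2` < 50) de-rate MS evidence; SVM and CSP evidence are de-rated by
confidence and profile divergence.

## Worked example

`examples/case_study_fusion.py` walks through the
beta-1,4-galactosyltransferase case study (true topology C134-C176,
C247-C266), where the SVM confidently backs a wrong bond:

```
frame of discernment: C134-C176, C247-C266, C134-C247
  MS   masses  {C247-C266}: 0.34; {C134-C176+C247-C266}: 0.33; {C134-C176}: 0.33; environment: 0.00
  SVM  masses  {C134-C247}: 1.00; environment: 0.00
  CSP  masses  environment: 1.00

yager     -> no bonds above zero (environment 1.000)
shafer    -> C134-C176=0.221, C134-C247=0.333, C247-C266=0.224 (environment 0.333)
dempster  -> total conflict between sources; the Dempster rule is undefined
campos    -> total conflict between sources; the Dempster rule is undefined
  maximum-weight matching: C134-C176, C247-C266
```

The MS column shows the subset masses: the two-bond subset
{C134-C176, C247-C266} gets mass 0.33 after normalisation. MS and SVM back
disjoint connectivities and the CSP scores (0.21) are too low to assign any
mass, so the joint evidence is totally conflicting: Dempster/Campos refuse,
Yager reports total ignorance, and the Shafer average keeps all three
candidates alive — the matching step then picks the two mutually consistent
true bonds (total belief 0.445) over the SVM's clashing bond (0.333).

The other examples each exercise one capability and print what the numbers
mean: `conflicting_evidence.py` (the Dempster conflict pathology),
`csp_prediction.py`, `ms_pipeline.py` (planted-topology recovery from noisy
synthetic spectra), `discount_and_fuse.py`, `evaluate_methods.py`
(sensitivity/specificity/MCC over the seven-protein benchmark fixtures).

A thin CLI wraps the same calls:

```sh
ssfuse simulate --seed 7 --out-dir bench/       # synthetic benchmark
ssfuse fuse --evidence bench/evidence.tsv --rule shafer --out fused.tsv
ssfuse csp --fasta query.fa --refdb refdb.tsv --out csp_ev.tsv
ssfuse ms-score --fasta protein.fa --spectra run.mgf --out ms_ev.tsv
ssfuse eval --pred pred.tsv --truth bench/truth.tsv
```

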