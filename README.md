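# nucfree

Equilibrium modeling of competitive transcription-factor (TF) and nucleosome
binding on genomic DNA, built to ask a specific question of chromatin biology:
how much of nucleosome positioning — and in particular of the nucleosome-free
regions (NFRs) found at promoters — is explained by nucleosome sequence
preferences, by steric "statistical" positioning, and by sequence-specific TFs
that compete nucleosomes away and thereby carve NFRs.

It is aimed at computational biologists who want an exact, tested
implementation of the thermodynamic competition model together with the full
evaluation pipeline around it: reference nucleosome/linker maps from
MNase-style read data, a mutual-information quality score, cross-validated
parameter fitting, per-TF ranking with shuffled-matrix controls, and
enrichment statistics — all runnable without any external datasets thanks to
a first-class synthetic-data generator with recorded ground truth.

## The model

Every binding species f (each TF, and the nucleosome) occupies a fixed
footprint of l_f bp. A configuration σ is any placement of non-overlapping
sites on the genome; its statistical weight is a product over placed sites,

    P(σ) ∝ ∏_{sites (f, j) ∈ σ} q_f(j),
    q_f(j) = exp( ln c_f − γ_f E_f(j) − E0_f ),

with c_f the factor's concentration, E_f(j) the sequence energy of the window
starting at j (in kT; β = 1), γ_f ≥ 0 a specificity scale (γ = 0: no sequence
preference; γ = 1: the base model), and E0_f a calibration offset chosen so
that all factors have equal overall affinity for the genome. TF energies come
from a position weight matrix w_f(i, α) under the mismatch convention

    E_f(s) = Σ_i [ ln w_f(i, α_max,i) − ln w_f(i, s_i) ]  ≥ 0,

so the consensus site has energy exactly 0. Nucleosome energies come from a
per-window energy track or from the built-in dinucleotide model (16
log-propensities weighted by a ~10.2 bp cosine across the 147 bp footprint),
centered and scaled by γ_nuc.

The partition function Z = Σ_σ ∏ q and all marginal site probabilities
("posteriors") P_f(j) = F(j) q_f(j) R(j + l_f)/Z are computed exactly by a
forward/backward recursion over the genome,

    F(i) = F(i−1) + Σ_f q_f(i − l_f) F(i − l_f),

numba-accelerated and numerically stabilized, with a brute-force enumerator
as an independent oracle and an exact stochastic-traceback sampler for whole
configurations. Per-base occupancies satisfy Σ_f n_f(i) + free(i) = 1
everywhere.

Predictions are scored against a reference map of nucleosome and linker
regions by the quality score

    ρ = max_c I(prediction > c ; annotation) / H(annotation)  ∈ [0, 1],

the fraction of the annotation's information captured after thresholding the
median predicted nucleosome occupancy per region at the best critical
occupancy c. Concentrations and specificity scales are fitted by maximizing ρ
(simulated annealing + Nelder–Mead) under stratified k-fold cross-validation;
individual TFs are ranked by the paired z-statistic of their held-out ρ gain
over the nucleosome-only model, with column-shuffled weight matrices as the
null control.

## Worked example

```python
from nucfree.synthetic_data import make_scenario
from nucfree.thermo_core import compute_occupancy
from nucfree.workflows import scenario_reference_map
from nucfree.scoring import region_medians, quality_score, labels_from_regions

# 50 kb genome, 10 genes, one causal TF whose consensus sites carve an NFR
# in every promoter; 4 noisy read datasets sampled from the exact model
sc = make_scenario("nfr_carving", seed=7, genome_length=50_000, n_genes=10)

occ = compute_occupancy(sc.factors, sc.genome, sc.nucleosome_model)
print(f"nucleosome coverage: {occ.occupancy['nucleosome'].mean():.3f}")

calls, ref = scenario_reference_map(sc)   # peak calling + consensus map
regions = ref.regions()
meds = region_medians(occ.occupancy["nucleosome"], regions)
q = quality_score(meds, labels_from_regions(regions))
print(f"quality score rho = {q.rho:.3f} (MI* = {q.mi_star:.3f} nats, "
      f"H = {q.entropy:.3f} nats, c* = {q.c_star:.2f}, AUC = {q.auc:.3f})")
```

prints

```
nucleosome coverage: 0.786
quality score rho = 1.000 (MI* = 0.248 nats, H = 0.248 nats, c* = 0.89, AUC = 1.000)
```

The genome is 78.6% covered by nucleosomes at equilibrium; classifying the
annotated regions by whether their median predicted occupancy exceeds
c\* = 0.89 reproduces the reference annotation perfectly (ρ = 1: the
prediction captures all of the annotation's 0.248 nats of label entropy) —
as it should here, since the map was built from reads sampled from this very
model.

A thin CLI mirrors the library (`nucfree simulate | energies | occupancy |
callnucs | refmap | score | fit | enrich`); see `nucfree --help`.

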