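# Methods

## Model

The package computes exact equilibrium statistics of all non-overlapping
binding configurations of a set of DNA-binding factors — sequence-specific
TFs plus the nucleosome, treated as one more factor with a 147 bp
footprint — on a genome. The model is grand-canonical in spirit: each placed
site of factor f contributes a Boltzmann weight
q_f(j) = exp(ln c_f − γ_f E_f(j) − E0_f), and configuration probabilities
are products of site weights divided by the partition function. Energies are
in kT (the inverse temperature is absorbed into the specificity scales).

Assumptions worth stating explicitly:

* **Equilibrium.** Occupancy profiles are thermodynamic averages;
  ATP-dependent remodeling is assumed to re-equilibrate positions rather
  than bias them.
* **Hard-core exclusion only.** Factors interact solely by mutual exclusion;
  there are no cooperative or anti-cooperative energy terms, no partially
  unwrapped nucleosome states, and no wrap-around at chromosome ends.
* **Additive site energies.** TF energies are sums of per-position
  contributions from the weight matrix (the log-ratio mismatch form, with
  the consensus anchored at E = 0). The additive offset freedom is entirely
  absorbed by the calibration E0_f, which is fixed so that the genome-wide
  mean of exp(−γ_f E − E0_f) over all valid windows on both strands is
  exactly 1 ("equal overall affinity for the genome"); a global shift of all
  energies followed by recalibration leaves every observable unchanged
  (tested).
* **Strand handling.** The two orientations of a TF site are two site types
  sharing one concentration; their weights are summed per start position.
  Nucleosome energies are strand-symmetrized by averaging the Boltzmann
  weights of a window and its reverse complement.
* **Ambiguity codes.** Any window containing N is unbindable (weight 0).

## Numerics

The forward/backward partition sums use the linear-domain recursion with
block rescaling: running values are kept relative to a carried log scale
that is bumped past 1e100, and per-position log scales are recorded, so exact
log partition sums and posteriors are recovered without overflow. The
binding contract is agreement with exhaustive enumeration to 1e-9 relative
on small instances (50 random instances per test run; observed agreement is
~1e-13). Forward and backward logZ must agree to 1e-9 relative, and
occupancy conservation Σ_f n_f(i) + free(i) = 1 is asserted at every
computation to 1e-9. The recursions and the stochastic traceback are
numba-compiled; the traceback uses precomputed per-position choice
probabilities, so sampling is exact and free of transcendentals in the
inner loop.

The quality score ρ uses natural logarithms internally and is
base-invariant. The threshold scan is exact over all midpoints between
distinct region medians (plus ±∞), classification is strictly
"median > c → nucleosome", and ties in mutual information resolve to the
smallest threshold. ρ is invariant under strictly monotone transforms of
the occupancy track (property-tested). Region medians are exact per-base
medians; even-length regions take the mean of the central pair.

Coverage normalization maps signal to probability via p = exp((s − b)/a):
b is the maximum outlier-trimmed signal (so the largest retained signal maps
to p = 1) and a > 0 is found by monotone root-finding so that the clamped
mean over all positions equals the target (default 0.81, configurable);
trimmed outliers are clamped into [0, 1]. Degenerate constant signals map
identically to the target.

Peak calling is GeneTrack-style: Gaussian smoothing of read midpoints
(σ = 20 bp default), greedy acceptance of local maxima in decreasing height
with a 147 bp exclusion zone, and a height cutoff in reads-equivalent units
(smoothed density × σ√(2π)). The function default (3.0) suits read depths of
a few reads per nucleosome; for deeply sampled data the cutoff should scale
with depth, and `workflows.depth_scaled_cutoff` provides the conversion
(occupancy fraction × cells × reads per nucleosome; the scenario pipelines
use occupancy 0.5). Consensus maps re-run the same caller on the pooled
per-dataset call dyads, retain consensus nucleosomes supported by at least
`min_support` datasets (default: all; matching within half the exclusion
zone, ties toward the smaller coordinate), and define linkers as maximal
intervals covered by no dataset's call footprint, split into short linkers
(< 50 bp) and NFRs. Position reproducibility reports the sample standard
deviation (ddof = 1) of matched per-dataset dyads.

## Fitting

The objective is −ρ on training regions. Concentrations are optimized in
natural log (bounds [−30, 10]), specificity scales linearly (bounds [0, 5]);
E0 recalibration is folded into every objective evaluation. The default
optimizer is simulated annealing (Metropolis; T0 = 1.0 on the ρ scale,
cooling ×0.9, 20 proposals per temperature, T_min = 1e-3, proposal SD 0.3
for log-concentrations and 0.1 for γ) followed by a Nelder–Mead polish; all
schedule knobs are configurable, and a light schedule plus a shared coarse
grid optimizer exist for the many small two-parameter fits of per-TF
ranking. Because ρ is rank-based and therefore piecewise constant in the
parameters, optima are plateaus; fits start from a neutral default
(γ = 0.5, ln c = 0) and are deterministic given the seed.

Cross-validation uses stratified k-fold splits (default k = 5) so every fold
carries both labels. TF ranking fixes the nucleosome at its fitted optimum,
fits each TF's (ln c, γ) per fold on the training regions, and forms the
paired per-fold gain Δρ on held-out regions; the ranking statistic is
z = mean(Δ)/SE(Δ) across folds. Folds are shared between all TFs and the
baseline so the statistic is genuinely paired. The promoter-gain statistic
fits per fold on genome-wide training regions and evaluates the promoter
subset with each fold's parameters against the fixed nucleosome-only model;
per-fold promoter test subsets are too small at desk scale to carry both
labels reliably.

Factor characterization reports the genome coverage fraction
φ_f = (l_f/L) Σ_j P_f(j), posterior-weighted mean and SD of the model's
γ-scaled site energies, and a binding-site entropy. The default entropy is
that of the normalized site distribution, S = −Σ_j π_j ln π_j with
π_j = P_f(j)/Σ P_f(j) — high when coverage comes from many weak sites; an
alternative per-site binary entropy is available behind a flag. Neither form
is claimed to be anything but this package's definition.

Link-level enrichment reports the exact fold (k/n)/(K/N) over link counts
and an approximate p-value treating each link as an exchangeable draw with
success probability |top|/|TFs| (binomial tail, flagged `approximate`);
category enrichment is the classic hypergeometric test.

## Synthetic study conditions

The generator replaces the real inputs (genome, curated WM collection,
nucleosome model, MNase datasets, interaction database) with fully specified
synthetic counterparts; every quantity is a pure function of (parameters,
seed), and the exact model occupancy is the distributional truth for all
sampled data.

Defaults, chosen once: 200 kb genome at GC 0.39, 40 genes spaced 5 kb
(alternating strands, 1650 bp bodies), 20 TFs of length 8 (information
content 10 bits for causal TFs, 7–13 bits for decoys), 4 read datasets of
2000 cells each, Poisson(0.05) reads per placed nucleosome with Gaussian
positional noise (SD 20 bp), planted-site mutation rate 5%. The built-in
dinucleotide nucleosome model (A/T-favoring, G/C-penalizing propensities
under a 10.2 bp cosine) yields a raw energy SD of ≈3.5 kT on random
sequence. The true nucleosome concentration default (ln c = 1.0) was
calibrated once so that genome coverage is ≈0.8, the figure generally
quoted for yeast chromatin, and then frozen; causal TFs use ln c = −4,
γ = 1, which gives them ≈90% occupancy at planted consensus sites.

Promoter architecture of carving scenarios mimics yeast: three TF sites at
TSS−200/−130/−60 (one causal TF per promoter in `nfr_carving`, three in
`mixed`), producing an NFR over roughly [−210, −50], with the +1 nucleosome
slot flush against the NFR edge (dyad ≈ TSS+45) and further slots every
165 bp through the gene body. Phasing scenarios overwrite the slots with a
10.2 bp-periodic A/T vs G/C composition so positioning there is
sequence-driven. The `mixed` scenario uses weak nucleosome specificity
(γ_nuc = 0.5), the regime the fitted models of this kind actually occupy;
at strong specificity the synthetic landscape develops deep sequence-driven
NFRs inside promoter windows, a qualitatively different regime. `null` has
no planted structure and γ_nuc = 0.

What the generator does **not** emulate: MNase sequence bias (treated as a
confounder, not a mechanism), fragment-end geometry (midpoints only),
regulatory heterogeneity between promoters, chromosome-scale features, or
the real yeast genome's base composition structure. Passing tests therefore
demonstrate correctness and calibration of the machinery under the model's
own assumptions, not performance on real chromatin data.

## Known limitations

* ρ is brittle at desk scale: with a few hundred scored regions each
  misclassified region costs several percent, so subset scores (e.g., ~50
  promoter-NFR regions) carry large granularity.
* The z-statistics of column-shuffled control matrices are conservatively
  biased negative at desk scale (mean ≈ −0.7 over 50 controls): fitting a
  useless TF's two parameters on a few hundred training regions degrades
  held-out ρ by an amount comparable to fold noise. No shuffled control
  scores better than chance (the scientifically meaningful direction), but
  the z null is *not* standard normal at this problem size; that calibration
  emerges only with region counts orders of magnitude larger, as in
  full-genome maps.
* The dinucleotide nucleosome model is a synthetic stand-in built for
  interface compatibility and qualitative realism (periodicity, A/T
  preference); its parameters are not trained on data.
* Fits are derivative-free on a piecewise-constant objective; reported
  optima are plateau representatives, and concentration parameters are only
  weakly identified in saturated-coverage regimes.
* The per-TF ranking's grid optimizer trades fit resolution for speed;
  schedule and grid are configurable when finer fits are wanted.
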