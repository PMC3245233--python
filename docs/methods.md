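# Methods

## The model

Protein sequence evolution is modelled as a reversible continuous-time
Markov chain on the 20 amino acids. The generator factorises as
`Q = S · diag(π)`: off-diagonal rates `q_ij = s_ij π_j`, where `S` is a
symmetric non-negative *exchangeability* matrix (190 free entries for
proteins) and `π` the equilibrium frequencies. Diagonals make rows sum to
zero, and `Q` is rescaled to one expected substitution per unit time so
branch lengths read as substitutions per site. Transition probabilities on
a branch of length `t` are `P(t) = exp(Qt)`. Equilibrium frequencies are
always the empirical residue counts of the alignment at hand — never free
parameters.

The package's central idea is a three-step procedure for building
alignment-specific exchangeability matrices without over-fitting:

1. **Specialist library.** For each of `m` training alignments (with
   trees), estimate all exchangeabilities by maximum likelihood (the REV
   model, the amino-acid analogue of GTR). Flatten each fitted `S` into a
   190-vector; stack them as columns of a non-negative matrix `V`
   (190 × m).
2. **Factorization.** Compute non-negative factorizations `V ≈ W·H` over a
   range of ranks `r` by minimising the squared Frobenius error. Columns
   of `W` are *basis matrices*; columns of `H` are per-training-alignment
   weights.
3. **Mixture fit for a new alignment.** Model the new alignment's
   exchangeabilities as `S = Σ_i w_i B_i` with `w_i ≥ 0`. Optimise the
   weights and branch lengths jointly by maximum likelihood for each rank,
   then pick the rank minimising AICc,

   `AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1)`,

   with `n` = number of alignment sites and `k` = number of mixture
   weights. Branch lengths are excluded from `k` (extra taxa add branch
   parameters *and* the information to estimate them, and including them
   makes the correction term blow up when branches approach sites).

The same mixture machinery over a fixed bundle of eight published
matrices (Dayhoff, JTT, WAG, rtREV, mtMAM, mtREV24, HIVwithin,
HIVbetween) is the *Mixture of Existing Rates* (MOER) model. Because every
fixed matrix is a vertex of the MOER simplex, MOER's likelihood is never
below the best single fixed model; AICc arbitrates whether the extra
weights are warranted.

### Scale conventions

Rate and time are confounded: scaling `S` up and branch lengths down
leaves the likelihood unchanged. Three conventions pin this down.

- Every basis or bundle matrix is pre-normalised to unit mean rate
  (`−Σ π_i q_ii = 1`) before mixing — under the *reference frequencies*
  (mean of the training alignments' empirical frequencies) for NNMF bases,
  under the test alignment's empirical frequencies for MOER bundles.
- Mixture weights live on the probability simplex, `Σ w_i = 1`. The
  simplex removes exactly the scale freedom and nothing else. The
  parameter count still uses `k = r` (configurable to `r − 1`): the
  procedure optimises over the number of weights and their values, and the
  reported convention is recorded in output manifests.
- During REV estimation one reference exchangeability (the first free
  entry) is pinned and the rest are optimised as logs of positive reals;
  the returned matrix is renormalised to unit mean rate under the
  alignment's empirical frequencies. Pinning versus post-hoc normalisation
  is cosmetic — same likelihood surface — but the choice is stated in
  output headers.

## Algorithms and numerical choices

**Likelihood.** Felsenstein pruning over compressed site patterns with
per-node, per-pattern rescaling (triggered below 1e−100) against
underflow. Gaps and ambiguity codes (X, B, Z, J, ?, and anything outside
the alphabet) are fully missing data: all-ones partial vectors, excluded
from frequency counts. `P(t)` comes from the eigendecomposition of the
symmetrised generator `diag(√π) Q diag(1/√π)` — exact for reversible `Q` —
with scipy's scaling-and-squaring as fallback for non-reversible input;
tiny negative probabilities are clamped to zero and rows renormalised
(error if a row sum deviates from 1 by more than 1e−8). Empirical
frequencies are floored at 1e−6 and renormalised so residues absent from
an alignment never create absorbing states.

**Rate variation.** Discrete gamma with equal-probability categories
represented by their conditional means (4 categories by default), mean
fixed at 1; `alpha = inf` degenerates to the single-rate model. Training
libraries default to a single rate class; gamma is available everywhere as
an option.

**Branch lengths.** Coordinate-wise bounded Brent searches on
[1e−8, 20], cycling until a full cycle gains < 1e−6 lnL (max 50 cycles;
warn and return the best found otherwise).

**REV estimation.** Alternating rounds: L-BFGS on the free
log-exchangeabilities, then branch-length cycles, until a round gains
< 1e−4 lnL (max 200 rounds). The 1-step variant pins to zero every pair of
residues whose codons (standard nuclear code, 61 sense codons, hard-coded)
cannot interconvert by one nucleotide change; 75 of the 190 pairs remain
free.

**NNMF.** Lee–Seung multiplicative updates for the Frobenius objective,
with a 1e−12 additive floor in denominators and on all entries of W and H
(zeros are absorbing under multiplicative updates). Initial entries are
i.i.d. uniform on (0, 1], W scaled by mean(V)/r; per-restart seeds derive
from a master seed. Default schedule: 20 random restarts × 2000 burn-in
iterations, then 5000 refinement iterations on the best candidate, with an
early stop when the relative objective change stays below 1e−10 for 10
iterations. Rank sweeps additionally warm-start each rank from the
previous rank's factors padded with one small random column, and keep the
better of warm and cold candidates — this guarantees the SSE-versus-rank
curve is monotone, which pure restarts only achieve stochastically.
Library columns are normalised before factorizing (their scale is
meaningless given free branch lengths); basis columns are normalised to
unit mean rate afterwards with the compensating rescale of H rows, leaving
`W·H` unchanged. All conventions are recorded in the basis-set manifest.

**Weight fitting.** The simplex is parameterised by r−1 log-ratio
coordinates; multi-start (uniform, best single component, random Dirichlet
— 3 starts by default) guards against local optima, alternating L-BFGS
steps with branch-length cycles until a round gains < 1e−4 lnL. Points
where the combined matrix becomes reducible (possible on the simplex
boundary with sparse bases) are handled by returning a large finite
penalty rather than failing. Ranks whose AICc correction is undefined
(`n − k − 1 ≤ 0`) are skipped with a warning; AICc ties break toward the
smaller rank. A flat `2·ln(#candidates)` penalty for selecting across the
sweep (≈ 7.4 for 40 candidates) is available as a diagnostic but not
applied.

**Joint factorization likelihood.** The summed pruning log-likelihood of
the training set under the basis and coefficient columns is exposed as a
diagnostic only; the factorization itself is always fit by least squares,
which approximates the likelihood-based objective one would ideally
maximise.

**Robinson–Foulds.** Trees are treated as unrooted; the distance is the
symmetric difference of non-trivial bipartition sets, ignoring branch
lengths. Polytomies contribute exactly the splits they induce.

**Property correlations.** Basis columns are correlated (Pearson, over the
190 pairs) against |Δproperty| for five residue properties — Grantham's
chemical composition, polarity and volume, standard free-amino-acid
isoelectric points, and Kyte–Doolittle hydropathy — shipped as an editable
CSV with provenance noted in its header. Significance is one-tailed
negative at per-test alpha 0.01 (0.05 Bonferroni-corrected across the five
properties), giving the critical value −0.16867 at 190 pairs. The Stanfel
(1996) five-class partition, also a data file, only orders residues for
matrix display.

## The synthetic benchmark

`simulate` generates everything the pipeline needs: random
coalescent-style topologies (uniform joins, branch lengths i.i.d.
exponential with mean 0.1 — moderate divergence comparable to curated
protein-family trees), alignments evolved site-by-site with exact
transition probabilities (root states from π, optional per-site gamma
category draws matching the discretised likelihood exactly), and complete
train/test fixtures: a ground-truth basis of sparse lognormal columns
(each forced to connect all states via a random spanning tree, so every
basis alone is irreducible), Dirichlet mixing weights per alignment, and
recorded truth. Everything is a pure function of the seed.

What the simulator does *not* emulate: indels (gaps appear only if placed
by hand), alignment error, site-to-site composition heterogeneity,
non-reversible or non-stationary evolution, and the size distribution of
real curated corpora. Passing recovery tests therefore demonstrates
correctness of the estimators under the model's own assumptions, not
robustness to their violation on real data.

### Problem sizes

Test and acceptance runs use deliberately small instances chosen so the
full pipeline exercises every code path in minutes on one core: 4-state
alphabets for REV recovery (16 taxa × 2000 sites) and for the
end-to-end pipeline (12 training alignments of 1500–2000 sites, ranks
1–4, one held-out alignment of 400–500 sites — held-out alignments
smaller than training ones, as in realistic use), and the full protein
alphabet for mixture-weight recovery (20 taxa × 1000 sites) and the MOER
comparisons (8–10 taxa, 300–800 sites). The statistical logic is
scale-free; larger instances only sharpen the same comparisons.

The 12-alignment training set matters for rank selection: NNMF averages
the per-alignment REV estimation noise across columns, and with too few
or too short training alignments the residual basis error is itself
detectable by a large held-out alignment, dragging the selected rank
upward — the same over-fitting pressure the AICc step exists to resist.

## Known limitations

- REV estimation at the full 190-parameter protein scale uses numerical
  gradients and is slow (hours, like any unaccelerated REV fit); the
  package is tuned for library construction at reduced alphabets and for
  protein-scale *mixture* fitting, which is cheap.
- NNMF reaches a local minimum; restarts mitigate but do not remove
  initialisation sensitivity, and basis matrices are identifiable only up
  to permutation and the fixed scale convention.
- The AICc observation count is the number of sites, ignoring
  phylogenetic correlation between sites only partially (sites are
  independent given the tree; the choice matters mainly through the
  small-sample term).
- Branch-length optimisation is coordinate-wise and can be slow to
  converge on star-like trees with long branches.
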