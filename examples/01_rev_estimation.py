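"""Estimate a general reversible (REV) exchangeability matrix by ML.

Simulates an alignment under a known 4-state model, fits all
exchangeabilities jointly with branch lengths, and compares the estimate
to the truth.
"""

import numpy as np

import ratemix as rm

alphabet = rm.toy_alphabet(4)
rng = np.random.default_rng(2)

pi = rm.FrequencyVector.uniform(alphabet)
S_true = rm.unflatten_exchangeabilities(rng.lognormal(0, 1, 6), alphabet).normalized(pi)
Q = rm.build_rate_matrix(S_true, pi)
tree = rm.random_tree(16, rng)
aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 2000, seed=11))

fit = rm.fit_rev(aln, tree, alphabet=alphabet)
r = np.corrcoef(fit.S_hat.flatten(), S_true.flatten())[0, 1]

print(f"log-likelihood: {fit.log_likelihood:.2f} after {fit.iterations} rounds")
print(f"true exchangeabilities:   {np.round(S_true.flatten(), 3)}")
print(f"fitted exchangeabilities: {np.round(fit.S_hat.flatten(), 3)}")
print(f"Pearson r (fit vs truth): {r:.4f}")
# r close to 1 means the 2000-site alignment identifies all six relative
# rates; on short alignments this correlation degrades — the motivation
# for mixing a few basis matrices instead of freeing every rate.
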