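"""Correlate basis exchangeabilities with residue property differences.

Published matrices stand in for basis columns here: their rates correlate
negatively with physicochemical property differences (dissimilar residues
exchange less), assessed against the one-tailed critical value.
"""

import numpy as np

import ratemix as rm

table = rm.load_property_table()
threshold = rm.negative_correlation_threshold(190, alpha_per_test=0.01)
print(f"one-tailed negative-correlation threshold at 190 pairs: {threshold:.5f}")

cols = {name: rm.load_bundled_matrix(name).flatten()
        for name in ("WAG", "JTT", "mtMAM")}
for name, col in cols.items():
    print(f"{name}:")
    for prop in table.properties:
        diff = rm.property_difference_vector(table, prop)
        r = rm.correlate_basis(col, diff)
        flag = "significant" if r <= threshold else "ns"
        print(f"  {prop:<22s} r = {r:+.3f}  ({flag})")
# strongly negative r: substitutions conserving that property dominate
# the matrix. Which properties matter varies between matrices — the
# motivation for letting each alignment weight basis matrices its own way.

partition = rm.load_stanfel_partition()
print("Stanfel display order:", "".join(rm.stanfel_order(partition)))
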