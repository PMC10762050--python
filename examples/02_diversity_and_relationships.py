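"""Diversity indices, IBS/MDS and Reynolds distances on synthetic data.

The fixture plants an inbreeding ladder (F = 0, 0.1, 0.4, two breeds
per rung); the table below shows how observed heterozygosity drops and
F_IS rises along it, and the Reynolds matrix shows between-breed
differentiation from their independently drawn allele frequencies.
"""

import numpy as np

from hrrscan import (breed_allele_freqs, classical_mds, diversity_table,
                     ibs_distance, paper_scale_fixture, reynolds_distance)

g, snpmap, samples, truth = paper_scale_fixture()

div = diversity_table(g, samples)
print("per-breed diversity (true F was 0, 0, 0.1, 0.1, 0.4, 0.4):")
print(div.round(3).to_string(index=False))

d, labels = ibs_distance(g)
mds = classical_mds(d, 2, labels)
print(f"\nMDS on IBS distances: C1 explains {mds.var_explained[0] * 100:.2f}%"
      f" and C2 {mds.var_explained[1] * 100:.2f}% of the positive spectrum")

freqs = breed_allele_freqs(g, samples, snp_ids=snpmap["snp_id"])
rey, breeds = reynolds_distance(freqs)
print("\nReynolds' distance between breeds (coancestry form):")
print(np.array2string(rey, precision=3), "\nbreeds:", breeds)
print("\nBreeds draw allele frequencies independently, so off-diagonal "
      "distances are large and similar; the diagonal is zero by definition.")
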