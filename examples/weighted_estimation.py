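"""Unbiased estimation of a graph observable from weighted samples.

The estimator is the self-normalized weighted average
sum(w_i Q_i) / sum(w_i).  Here Q is the indicator that two degree-2 nodes
of (3,2,2,2,1) are adjacent; the exact ensemble value is computed by brute
force for comparison.
"""

import numpy as np

from degsample import normalize_sequence, sample_graphs, weighted_average
from degsample.oracles import enumerate_realizations

seq = normalize_sequence([3, 2, 2, 2, 1])
graphs = enumerate_realizations(seq).graphs
exact = np.mean([((1, 2) in g) for g in graphs])

samples = list(sample_graphs(seq, 4000, master_seed=7))
values = [1.0 if (1, 2) in s.edges else 0.0 for s in samples]
res = weighted_average(values, [s.log_weight for s in samples])

print(f"P(edge between nodes 1 and 2) over all {len(graphs)} realizations")
print(f"  exact (brute force):  {exact:.4f}")
print(f"  weighted estimate:    {res.estimate:.4f} +/- {res.stderr:.4f}")
print(f"  effective sample size {res.ess:.0f} of {res.n_samples}")
print("\nThe estimate agrees with the enumerated ensemble value within error;")
print("the ESS shows how much sampling efficiency the weighting costs.")
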