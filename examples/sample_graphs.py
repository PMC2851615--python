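"""Draw weighted samples of simple graphs realizing a degree sequence.

Every sample is built hub by hub without rejection; its importance weight
w = (prod of allowed-set sizes) / (prod of hub-degree factorials) makes
uniform ensemble averages possible even though generation is biased.
"""

import math

from degsample import sample_graphs

seq = (3, 2, 2, 2, 1)
print(f"degree sequence {seq}")
for i, s in enumerate(sample_graphs(seq, 5, master_seed=1)):
    print(f"sample {i}: edges {s.edges}  ln w = {s.log_weight:.4f}"
          f"  (w = {math.exp(s.log_weight):.3f})")
print("\nln w = 0 would mean the sequence had a unique realization;")
print("larger weights flag samples the construction reaches less often.")
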