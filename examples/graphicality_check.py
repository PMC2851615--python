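"""Test integer sequences for graphicality with the Erdos-Gallai criterion.

A sequence is graphical when some simple graph has exactly those degrees.
The test needs an even degree sum and L_k <= R_k for k up to the Durfee
number, with both sides computed by recurrences.
"""

from degsample import compute_eg_tables, is_graphical, normalize_sequence

for raw in [(2, 2, 2), (1, 1, 1), (3, 3, 1, 1), (5, 4, 3, 2, 1, 1)]:
    seq = normalize_sequence(raw)
    verdict = is_graphical(seq)
    print(f"{raw}: {verdict.reason}" + (f" (k = {verdict.k})" if verdict.k else ""))

# The tables behind the verdict for one sequence:
eg = compute_eg_tables(normalize_sequence((3, 2, 1, 1, 1)))
print("\nsequence (3,2,1,1,1):")
print("  L_k (sums of k largest degrees):", eg.left_sums.tolist())
print("  R_k (Erdos-Gallai right side):  ", eg.right_sums.tolist())
print("  crossing indices x_k:           ", eg.crossing_index.tolist())
print(f"  Durfee number {eg.durfee}: inequalities beyond it hold automatically")
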