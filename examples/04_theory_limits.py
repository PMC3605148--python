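"""Why inference power fades into the past: closed-form coalescent limits.

Prints the expected inter-coalescent times (few lineages persist at old
time depths) and the probability that a small subsample spans the basal
split of the genealogy — the oldest recombination signal any subsample can
recover.
"""

from recombpast import expected_ti, p_root, p_root_split, total_expected_depth

print("Expected time with i ancestral lineages (units of N generations):")
for i in range(2, 6):
    print(f"  i={i}: E[T_i] = {expected_ti(i):.3f}")
print(f"Total expected depth, m=100 lineages: {total_expected_depth(100):.3f}")
print(f"  -> the final two lineages span {expected_ti(2) / total_expected_depth(100):.0%} of the tree")

print(f"\nP(a random quartet spans the basal split) = {p_root(4):.2f}")
print("Even a highly unbalanced split (232 vs 21 lineages, as at a locus")
print("with an introgressed deep clade) is seen by a single quartet with")
print(f"probability {p_root_split(232, 21, 4):.2f}.")
print("\nAll quartets that span the root see the *same* two deep branches,")
print("so drawing more quartets adds no information about the oldest")
print("recombination events — the hard limit on reconstruction depth.")
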