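"""How symbol order changes the cost of adaptive order-0 coding.

Codes the same multiset of 100,000 quantized-Gaussian symbols in three
arrangements: two sources concatenated (Z1), shuffled together (Z2), and
sorted (Z3).  With adaptive counts and periodic rescaling, locally
homogeneous arrangements cooperate with the probability-update mechanism:
the sorted stream costs a small fraction of the others.
"""

from acoqs import coding_order_experiment

sizes = coding_order_experiment(n=100_000, seed=1)
for name, label in (("Z1", "concatenated (two regimes)"),
                    ("Z2", "shuffled (stationary mixture)"),
                    ("Z3", "sorted (maximally clustered)")):
    print(f"{name} {label:32s}: {sizes[name]:7d} bytes")
print("Identical symbol multiset in all three; every size difference is an "
      "effect of coding order on the adaptive model.")
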