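"""Derive a row-mean quantizer from data with the DP machinery.

Tabulates empirical conditional quality distributions per (rounded) row
mean from synthetic reads with a wide per-read level spread, then finds the
contiguous 5-bin partition minimizing the prior-weighted KL distortion, and
reports the entropy cost of quantization.  The production codec ships a
fixed rule; this is the "solve the optimization yourself" path.
"""

import numpy as np

from acoqs import ConditionSet, compute_row_mean, entropy_gap, optimal_partition
from acoqs.synthetic import generate, preset

records = generate(preset("row-spread", n_reads=4000, read_len=60, seed=2))
means = np.array([round(compute_row_mean(r.quals)) for r in records])
qmax = max(int(r.quals.max()) for r in records)

levels = np.unique(means)
counts = np.zeros((levels.size, qmax + 1))
for i, lvl in enumerate(levels):
    for r in (rec for rec, m in zip(records, means) if m == lvl):
        np.add.at(counts[i], r.quals.astype(int), 1)

cs = ConditionSet.from_joint_counts(counts)
part = optimal_partition(cs, k=5, measure="kl")
h_m, h_q = entropy_gap(cs, part)

print(f"observed row means: {levels.min()}..{levels.max()} "
      f"({levels.size} distinct values)")
print("optimal contiguous 5-bin partition (by row-mean value):")
for s, e in part.bins:
    print(f"  [{levels[s]}, {levels[e]}]")
print(f"distortion objective L = {part.objective:.4f} bits")
print(f"H(X|M) = {h_m:.3f} bits, H(X|Q) = {h_q:.3f} bits "
      f"(gap {h_q - h_m:.4f} = entropy cost of using 5 bins)")
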