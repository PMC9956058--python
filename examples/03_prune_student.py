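"""Channel pruning of the lightweight student via BN-scale sparsity.

Builds the mobilenetv2-backbone student, randomizes its BN scales to imitate
a sparsity-trained state, derives the 80 % global threshold over pooled
|gamma|, reconstructs the pruned network, and verifies the parameter drop and
output preservation.
"""

import numpy as np

from distilharvest import NetworkSpec, build_student, prune_network
from distilharvest.slimmer import collect_gammas, global_threshold

spec = NetworkSpec(role="student", backbone="mobilenetv2", input_side=96,
                   width_multiple=0.5, depth_multiple=0.33, dropout=0.0)
net = build_student(spec)
rng = np.random.default_rng(0)
for _name, unit in net.bn_units():
    c = unit.bn.channels
    # imitate post-sparsity-training scales: many near zero, a few large
    unit.bn.weight.data = (rng.standard_normal(c)
                           * rng.choice([0.02, 1.0], c, p=[0.7, 0.3])
                           ).astype(np.float32)
net.eval()

gammas = collect_gammas(net)
thr = global_threshold(gammas, 0.8)
print(f"pooled prunable channels: {gammas.size}; "
      f"80% |gamma| threshold = {thr:.4f}")

pruned, mask, report = prune_network(net, 0.8)
print(f"parameters: {net.num_parameters()} -> {pruned.num_parameters()} "
      f"({pruned.num_parameters() / net.num_parameters():.1%} kept)")
print(f"pooled channel-removal fraction: {mask.removed_fraction():.3f} "
      f"(union alignment and the one-channel floor put some channels back)")
print("most-pruned layers:")
for row in sorted(report, key=lambda r: r["channels_after"]
                  - r["channels_before"])[:5]:
    print(f"  {row['layer']}: {row['channels_before']} -> "
          f"{row['channels_after']} channels")
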