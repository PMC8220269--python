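"""Size of combinatorial media-design spaces, and what an environment is.

Counting is closed-form (binomial sums), so even spaces far too large to
screen are sized instantly; enumeration is reserved for small spaces.
"""

from envdesign import (
    EnvironmentSpace,
    MediumSpec,
    build_medium,
    count_environments,
    enumerate_environments,
)
from envdesign.fixture import fixture_pool

# A 20-nutrient screen, combinations of up to 4 (plus the base medium alone):
print("20 nutrients, up to 4 at a time:",
      count_environments(20, 4, size_rule="up_to", include_empty=True))
# Every subset of 20 nutrients — the full factorial a lab could never run:
print("all subsets of 20 nutrients:   ",
      count_environments(20, 20, size_rule="up_to", include_empty=True))
# A large exploratory space: exactly 3 of 154 carbon sources:
print("exactly 3 of 154 sources:      ",
      count_environments(154, 3, size_rule="exact"))

# The packaged 10-nutrient pool gives a fully enumerable benchmark space:
space = EnvironmentSpace(fixture_pool(), max_nutrients=3, include_empty=True)
envs = enumerate_environments(space)
print(f"\npackaged space: {len(envs)} environments; first five:",
      [e.label() or "(base medium)" for e in envs[:5]])

# An environment becomes a medium by an equimolar split of 50 mM C in 400 ul:
env = envs[-1]
amounts = build_medium(env, MediumSpec(), space.pool)
print(f"medium for {env.label()}: " +
      ", ".join(f"{k}={v * 1e3:.4f} umol" for k, v in amounts.items()))
print("each environment carries 0.02 mmol of carbon in total")
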