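"""Probabilistic sensitivity analysis with CE-plane quadrants and CEAC.

Draws every uncertain parameter per iteration (beta for probabilities and
utilities, gamma for costs; zero-event parameters fixed; utilities shared by
both arms drawn once) and reruns the deterministic model each time.
"""

import numpy as np

from bchicea import bundled_defaults, bundled_life_table, ceac, default_settings, psa

out = psa(
    bundled_defaults("sentio"),
    bundled_defaults("osia"),
    default_settings(),
    bundled_life_table(),
    n_iterations=2_000,
    seed=42,
)

print(f"iterations: {out.n_iterations} (seed {out.seed})")
print("mean cost  (AUD):", {k: round(v) for k, v in out.mean_cost.items()})
print("mean QALYs      :", {k: round(v, 3) for k, v in out.mean_qalys.items()})
print("CE-plane quadrant shares:")
for q, share in out.quadrant_shares.items():
    print(f"  {q:28s} {share:6.1%}")
print(f"P(cost-effective at 50,000 AUD/QALY) = {out.probability_cost_effective(5e4):.3f}")
for wtp in (0.0, 20_000.0, 50_000.0):
    print(f"  CEAC at {wtp:>7,.0f}: {ceac(out, [wtp])[0]:.3f}")
print()
print("Most iterations fall in the dominant quadrant (cheaper, more")
print("effective); the CEAC gives the share of iterations with non-negative")
print("net monetary benefit at each willingness-to-pay.")
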