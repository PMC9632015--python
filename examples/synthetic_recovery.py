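"""Verifying the engine against synthetic worlds with known truth.

Generates a fully synthetic input bundle from known parameters, computes
the analytically implied deaths prevented or postponed by continuous
quadrature, and shows that the 25-bin pipeline recovers it.
"""

from tfamm import make_synthetic_bundle, run_model
from tfamm.fixtures import SyntheticConfig

config = SyntheticConfig(seed=11, mean_tfa_pct_energy=0.8, cv=0.5,
                         cap_fraction=0.5)
syn = make_synthetic_bundle(config)

print(f"Synthetic world: mean TFA {config.mean_tfa_pct_energy}% of energy, "
      f"cv {config.cv}, {sum(r.deaths for r in syn.bundle.mortality):,.0f} "
      f"CVD deaths/year")
print(f"{'scenario':9s} {'model DPP':>10s} {'truth DPP':>10s} {'rel err':>8s}")
for scen in ("cap", "ban"):
    got = run_model(syn.bundle, syn.scenarios[scen]).total("dpp")
    want = syn.truth.true_dpp[scen]
    print(f"{scen:9s} {got:10,.1f} {want:10,.1f} {abs(got - want) / want:8.2%}")

# The ground truth integrates the continuous log-normal exposure against
# the continuous log-linear RR on a 20,000-point grid; the only gap to
# the engine is its 25-bin midpoint discretization, which stays well
# under 1% in the model's operating range.
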