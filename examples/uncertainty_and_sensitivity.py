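"""Monte Carlo uncertainty intervals and deterministic sensitivity.

Propagates the sampling error of the meta-analytic relative risks and of
the market-derived exposure mean through the pipeline (5,000 draws), and
re-runs the model under deterministic assumption variants.
"""

from tfamm import make_brazil_fixture
from tfamm.uncertainty import DrawSpec, deterministic_sensitivity, monte_carlo

fixture = make_brazil_fixture()

print("95% uncertainty intervals (5,000 draws, seed 1):")
for key in ("A", "B", "C"):
    ui = monte_carlo(fixture.bundle, fixture.scenarios[key],
                     DrawSpec(n_draws=5000, seed=1))
    point, lo, hi = ui.quantities["dpp_total"]
    print(f"  scenario {key}: DPP {point:8,.0f}  (UI {lo:,.0f} - {hi:,.0f})")

# Each draw samples one RR per outcome and age band from a log-normal
# matched to the published CI, plus a joint perturbation of the exposure
# means; the UI is the 2.5th-97.5th percentile of the resulting DPP.

print("\nDeterministic sensitivity (PHO ban, % change in total DPP):")
frame = deterministic_sensitivity(fixture.bundle, fixture.scenarios["C"])
for row in frame.itertuples():
    print(f"  {row.variant:10s} {row.pct_change:+6.1f}%")

# Raising the theoretical-minimum exposure to 0.2% of energy barely
# moves the estimate (little baseline mass sits that low); scaling the
# excess relative risks by +-10% moves total DPP roughly +-9%.
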