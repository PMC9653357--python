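"""Reduce the 16-test motor battery to left/right component scores.

An oblique (promax) rotation PCA of the standardized battery yields two
correlated components, one per body side; scores are signed so impairment
is negative, and the proportion of impaired patients is read off directly.
"""

import strokepred as sp

basis = sp.generate_component_basis(372, 46, seed=1)
dataset, truth = sp.generate_disconnections(basis, 62, 5, 0.02, seed=1)
battery = sp.generate_motor_battery(truth, truth.mixing_weights, seed=1)
outcome = sp.fit_motor_outcome(battery)

for tp in sp.TIMEPOINTS:
    ve = outcome.variance_explained[tp]
    fc = outcome.factor_correlation[tp]
    imp = sp.impairment_proportion(outcome, tp)
    print(f"{tp:>3}: variance explained {ve:.1%}, factor correlation {fc:.2f}, "
          f"impaired left {imp['left']:.0%} / right {imp['right']:.0%}")
# Two components summarise the battery; their correlation reflects the
# generating left/right latent correlation, and scores below zero mark
# patients performing under the cohort mean.
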