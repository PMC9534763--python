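"""Segregated versus randomly mixed selectivity: the ePAIRS contrast.

Runs the ePAIRS nearest-neighbor-angle test on (1) the seven-dimensional mode
weights of a clustered population and (2) a synthetic population built from
random mixtures of the same activity modes; also compares two-mode angle
distributions against the mixture reference.
"""

import numpy as np

from popmodes import (
    GeneratorConfig,
    ModeWeightVectors,
    build_response_matrix,
    define_modes,
    epairs_test,
    generate_session,
    orthogonalize,
    pair_angle_distribution,
    split_trials,
    synthesize_mixture_population,
)

cfg = GeneratorConfig(
    n_units=300,
    n_prototypes=7,
    gain_sd=0.0,
    n_trials_per_condition={"CR": 80, "CL": 80, "ER": 16, "EL": 16},
    seed=2,
)
session, truth = generate_session(cfg)
matrix = build_response_matrix(session)
definition, _ = split_trials(session, seed=0)
modes = orthogonalize(define_modes(session, matrix.unit_ids, definition))
weights = ModeWeightVectors.from_modeset(modes)

seg = epairs_test(weights.weights, k=3, n_null=1000, seed=0)
print(f"clustered population: ePAIRS median NN angle {seg.median_angle_deg:.1f} deg, "
      f"p = {seg.p_value:.4f}  (p < 0.05 -> coding vectors cluster)")

mix = synthesize_mixture_population(modes, matrix, seed=0)
w_mix = np.linalg.lstsq(mix.component_timecourses.T, mix.rows.T, rcond=None)[0].T[:, :7]
res_mix = epairs_test(w_mix, k=3, n_null=1000, seed=0)
print(f"random-mixture population: ePAIRS p = {res_mix.p_value:.3f}  "
      f"(large p -> indistinguishable from a uniform continuum)")

ref_angles, _ = pair_angle_distribution(w_mix, 0, 1, top_fraction=0.2)
angles, p = pair_angle_distribution(weights, "stimulus", "choice", reference_angles=ref_angles)
near_axis = ((angles < 15) | (angles > 75)).mean()
print(f"stimulus-vs-choice coding angles: {100 * near_axis:.0f}% within 15 deg of an "
      f"axis; KS vs mixture p = {p:.2e}")
# angle mass at 0 and 90 degrees means neurons code one mode or the other —
# segregated populations — rather than random mixtures (mass near 45 degrees)
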