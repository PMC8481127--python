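"""Responsive fractions, cluster-number selection and the component model.

First: the trial-count-corrected probability that a neuron responds to
at least one task stimulus. Then the chronic-series analyses:
shuffled-inertia k-means on time-varying responsive fractions, and the
four-component (base / decay / task / learning) decomposition.
"""

import numpy as np

from catglm.responsiveness import (cluster_time_patterns, fit_component_model,
                                   responsive_probability, select_k)
from catglm.simulate import (AgentParams, PlantedKernels,
                             simulate_behavior_session, simulate_neural_session)
from catglm.spaces import build_category_space, reduce_to_category_stimuli

space = reduce_to_category_stimuli(
    build_category_space(6, 18.0, [0.04, 0.06, 0.08, 0.12, 0.16], 23.0, 0.1), 5)
trials = simulate_behavior_session(space, AgentParams(23.0, steepness=3.0),
                                   150, seed=1)
ori = str(trials["ori_index"].value_counts().idxmax())
kernels = PlantedKernels([
    {("offset", ""): np.array([0.2]),       # strong visual responder
     ("orientation", ori): 4.0 * np.exp(-0.5 * ((np.arange(7) * 0.5 - 0.5) / 0.5) ** 2)},
    {("offset", ""): np.array([0.2])},      # unresponsive neuron
])
session = simulate_neural_session(trials, kernels, 15.0, noise_sd=0.3, seed=2)

for n in range(2):
    p = responsive_probability(session, n, n_subsample=8, n_repeats=50, seed=3)
    print(f"neuron {n}: P(responsive to >= 1 stimulus) = {p:.2f}")
# subsampling 8 trials/stimulus 50 times corrects for variable trial counts

# --- chronic dynamics: 39 recordings from two planted archetypes ----------
rng = np.random.default_rng(4)
stable = np.array([0.8, 0.7, 0.6, 0.6, 0.55])     # no learning effect
recruited = np.array([0.5, 0.45, 0.5, 0.9, 0.85])  # post-learning increase
patterns = np.array([([stable, recruited][i % 2]) + rng.normal(0, 0.08, 5)
                     for i in range(39)])
solutions = cluster_time_patterns(patterns, k_range=range(2, 7),
                                  n_shuffles=50, seed=5)
print(f"\nselected cluster count: {select_k(solutions)} "
      f"(delta inertia per k: "
      f"{ {k: round(s.delta_inertia, 1) for k, s in solutions.items()} })")

labels = ["TC1", "TC2", "task_bs", "task_learned", "TC_final"]
fit = fit_component_model(patterns[1], labels, seed=6)
print("component weights of a 'recruited' recording:",
      {k: round(v, 3) for k, v in fit.weights.items()})
print("unique contributions (delta R^2):",
      {k: round(v, 3) for k, v in fit.delta_r2.items()})
# the learning component should dominate the recruited archetype
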