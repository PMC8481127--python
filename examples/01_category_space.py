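"""Build category spaces: the touch-screen grid and the reduced chronic space.

A category space is a grid of gratings (orientation x spatial
frequency) split by a linear boundary into a lick-left and a
lick-right category; stimuli exactly on the boundary are excluded.
"""

from catglm.spaces import build_category_space, reduce_to_category_stimuli

# 7 orientations spaced 15 deg x 7 spatial frequencies, 45 deg diagonal
touch = build_category_space(
    n_orientations=7, orientation_spacing_deg=15.0,
    spatial_frequencies=[0.03, 0.035, 0.04, 0.05, 0.07, 0.09, 0.11],
    boundary_angle_deg=45.0, boundary_offset=0.0,
)
print("touch-screen space:", touch.category_counts())
# -> 21 left + 21 right stimuli, the 7 on-diagonal stimuli excluded

# chronic-imaging space: 6 orientations x 5 SFs, boundary rotated to 23 deg
# (matching a typical rule bias), then reduced to the 10 stimuli nearest
# the boundary so each one collects many trials
chronic = build_category_space(
    6, 18.0, [0.04, 0.06, 0.08, 0.12, 0.16],
    boundary_angle_deg=23.0, boundary_offset=0.1,
)
reduced = reduce_to_category_stimuli(chronic, n_per_side=5)
active = reduced.active_stimuli()
print("\nreduced category stimuli (grid coordinates and signed boundary distance):")
print(active[["ori_index", "sf_index", "category", "signed_distance"]]
      .to_string(index=False))
# the signed distance (in grid steps) is the quantity psychometric
# curves are plotted against
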