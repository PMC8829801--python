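"""Recover injected degeneration as ipsi/contra ROI ratios.

Runs the full analysis on a phantom with known injected effects
(lambda1 x0.94 at week 6; lambda1 x0.98 and lambda23 x1.07 at week 29,
with 5% map noise) and prints the recovered tract-ROI ratios.
"""

import tractolesion as tl
from tractolesion import synthetic as syn

grid = syn.default_grid()
bundles = syn.default_bundles(grid, n_streamlines_cst=300, n_streamlines_transverse=100)
lesion = syn.default_lesion(grid)
database = syn.make_phantom_database(bundles, n_subjects=5, seed=0)
model, _ = tl.build_damage_model(database, lesion)

profile = syn.default_profile(seed=0, noise_sd=0.05)
scalars = {
    tp: syn.make_diffusion_maps(bundles, lesion, profile, tp)[0]
    for tp in ("W6", "W29")
}

table = tl.analyze_patient(model, lesion, scalars)
tract = table[table.roi == "tract"]
print(tract[["timepoint", "metric", "ipsi_mean", "contra_mean", "ratio"]]
      .to_string(index=False))

# Ratios near the injected factors: rlambda1 ~ 0.94 at W6 and ~ 0.98 at
# W29, rlambda23 ~ 1.00 then ~ 1.07 -- the early axial decrease and the
# later radial increase typical of secondary fiber degeneration.
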