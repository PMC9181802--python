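"""Sensitivity of CV prediction skill to the spatial kernel.

Reruns the same CV split under CAR priors with alpha_s from 0.1 to 0.9 and
Gaussian kernels over the default data-adaptive bandwidth sweep.
"""

import spatialmap as sm

paired, _ = sm.simulate_paired_datasets(
    n_pixels=150, n_genes=30, n_cells=250, n_types=4, seed=1)

grid = [("car", round(a, 1)) for a in (0.1, 0.3, 0.5, 0.7, 0.9)]
grid += [("gaussian", b) for b in
         sm.default_bandwidths(paired.spatial.coords)[:3]]

table = sm.kernel_sensitivity(paired, n_test=6, kernel_grid=grid, seed=1)
print(table.round(3).to_string(index=False))
print("\nA flat profile across configurations means the prediction is "
      "robust to the kernel choice; the data were generated under "
      "CAR alpha_s = 0.5.")
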