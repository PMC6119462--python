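"""Ordinary kriging on a simulated field: variogram fit, prediction, variance.

Simulates a Gaussian random field with a known variogram, samples it at 120
locations, refits the variogram from the sample, and kriges a target point.
"""

import numpy as np

from rfsp import GridSpec, VariogramModel
from rfsp.krige import empirical_variogram, fit_variogram, ok_predict
from rfsp.synthfields import FieldSpec, make_dataset, sample_design, simulate_grf

grid = GridSpec(origin=(0.0, 40.0), cell_size=1.0, nrows=40, ncols=40)
true_vgm = VariogramModel("exponential", nugget=0.1, psill=1.0, range_param=8.0)

field = simulate_grf(FieldSpec(grid=grid, vgm=true_vgm, seed=1))
locs = sample_design(grid, 120, seed=2)
ps = make_dataset(field, locs, seed=3)

emp = empirical_variogram(ps)
fitted = fit_variogram(emp, family="exponential")
print(f"true model:   nugget={true_vgm.nugget:.2f} psill={true_vgm.psill:.2f} "
      f"range={true_vgm.range_param:.1f}")
print(f"fitted model: nugget={fitted.nugget:.2f} psill={fitted.psill:.2f} "
      f"range={fitted.range_param:.1f}")
# the fitted parameters should land near the generating ones; the range is
# the hardest to pin down from 120 points

target = np.array([[20.0, 20.0]])
res = ok_predict(ps, target, fitted, keep_weights=True)
i, j = grid.cell_index(target[:, 0], target[:, 1])
print(f"prediction at (20, 20): {res.predictions[0]:+.3f}  "
      f"(truth {field.layers['field'][i[0], j[0]]:+.3f})")
print(f"kriging SD: {np.sqrt(res.variances[0]):.3f}   "
      f"weights sum: {res.weights[0].sum():.6f}")
# the weight sum is exactly 1 (unbiasedness constraint); the kriging SD is
# the model-based prediction error
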