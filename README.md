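# se2rec

Image analysis and reconstruction with the discrete **SE(2) group wavelet
transform**, modeled on the primary visual cortex: Gabor receptive fields
analyze an image over all orientations, a cortical-style
orientation-preference map keeps only one orientation per position, and a
reproducing-kernel *project-and-replace* iteration attempts to recover the
full transform — and hence the image — from that downsampled record.

The package is written for computational neuroscientists and applied
harmonic analysts who want a concrete, testable implementation of this
pipeline: filter banks and frame diagnostics, the range projection, feature
maps (uniform random, pinwheel-shaped, constant), the completion iteration
with its error trace, a dense linear-algebra oracle for solvability at desk
scale, and synthetic phantoms standing in for natural photographs.

## The model

An `N x N` image `f` is analyzed with `M` rotated Gabor filters.  In the
frequency domain each filter is a Gaussian of width `s` centred at radius
`p` along orientation `theta_j = 2*pi*j/M`:

    psi_hat_j(xi) = exp(-|xi + p (cos theta_j, sin theta_j)|^2 / (2 s^2))

and the transform is the stack of circular convolutions
`W f(x, j) = (f * psi_theta_j)(x)`, a complex `N x N x M` array.  The sum of
squared filter magnitudes, the Calderon function
`C(xi) = sum_j |psi_hat_j(xi)|^2`, controls invertibility: its extrema
`A <= B` over a frequency ball of radius `R` are the frame bounds of `W` on
images bandlimited to that ball, and the dual filters
`gamma_hat_j = chi_B psi_hat_j / C` invert the transform there
(`W*_gamma W_psi f = f`).

The range of `W_psi` on bandlimited images is a reproducing kernel subspace
of stacks; `P = W_psi W*_gamma` is the orthogonal projection onto it.  An
orientation-preference map `Theta` keeps only the entries `(x, Theta(x))`
of a stack (the selection `Q`).  Given the restricted data
`F_0 = Q W_psi f`, the project-and-replace iteration

    H_n = P F_{n-1},        F_n = H_n - Q H_n + F_0

converges to `W_psi f` exactly when `Ker(Q) ∩ Ran(P) = {0}`, at the
geometric rate given by the spectral radius of `Q_perp P`.  Reconstruction
quality is tracked by the percent RMS error of the read-out
`Delta_n = 100 ||f - Re W*_gamma H_n|| / (255 N)`.

## Worked example

```python
import numpy as np
from se2rec import *

params = BankParams(n=512, m=12, s=51.0, p=170.0)
bank = gabor_bank(params)
bounds = frame_bounds(calderon(bank), radius=252.0)
print(f"A = {bounds.lower:.4e}, B = {bounds.upper:.4f}")
print(f"B/A = {bounds.ratio:.1f}, condition = {bounds.condition_number:.1f}")

dual = dual_bank(bank, 252.0)
img = phantom(PhantomSpec(n=512, kind="powerlaw", beta=1.2, seed=11))
limited = bandlimit(img, 252.0)
theta = random_map(512, 12, seed=21)
f0 = restrict(se2_forward(limited, bank), theta)
trace = project_and_replace(f0, theta, bank, dual,
                            IterationConfig(max_iter=500, record_stride=100),
                            reference=img)
for it, d in zip(trace.iterations, trace.deltas):
    print(f"iteration {it:4d}: Delta = {d:.3f}%")
```

prints

```
A = 1.7934e-04, B = 1.1038
B/A = 6154.8, condition = 78.5
iteration    1: Delta = 51.278%
iteration  101: Delta = 6.043%
iteration  201: Delta = 3.490%
iteration  301: Delta = 2.565%
iteration  401: Delta = 2.100%
```

The frame ratio `B/A ≈ 6.2e3` (condition number 78.5) says the transform is
invertible but appreciably ill-conditioned on the analysis ball; the error
trace shows the completion recovering the image from one orientation per
pixel, from 51% of the 8-bit range after one projection down to a few
percent after a few hundred iterations (for this phantom the curve
flattens toward a floor near 1% set by its spectral tail outside the
analysis ball — see `docs/methods.md`).  A constant map (`constant_map`)
turns the same machinery into plain deconvolution by a single Gabor filter,
and pinwheel maps (`pinwheel_field` + `quantize_map`) interpolate between
the two regimes through the wavenumber `rho`.

The same pipeline is scriptable from the shell:

```bash
se2rec diagnose --n 512 --m 12 --s 51 --p 170 --r 252
se2rec phantom --n 512 --seed 11 --out phantom.png
se2rec reconstruct --phantom-kind powerlaw --phantom-seed 11 \
    --map-kind random --map-seed 21 --iterations 500 --out run/
```

## Layout

- `se2rec.bank` — Gabor banks, Calderon profile, frame bounds, dual filters
- `se2rec.transform` — forward/adjoint transforms, bandlimiting
- `se2rec.projection` — range projection and reproducing-kernel slices
- `se2rec.maps` — feature maps, selection operator, pinwheel detection
- `se2rec.reconstruct` — project-and-replace iteration, error metric
- `se2rec.oracle` — dense solvability/convergence oracle at desk scale
- `se2rec.phantom` — synthetic 8-bit test images
- `se2rec.io`, `se2rec.cli` — file formats and the `se2rec` command

See `docs/methods.md` for modeling choices, parameters and limitations.
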