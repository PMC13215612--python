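"""Exercise the conditional normalizing flow directly: exact invertibility,
analytic log-determinants, and conditional density evaluation.

A flow step is actnorm -> invertible multi-head linear -> affine coupling;
the forward map sends latents to the standard-normal base space while
accumulating log|det J|, so log p(z|x) = log N(f(z); 0, I) + log|det J|.
"""

import numpy as np

from pepflow.flow import PriorFlow
from pepflow.nn import Tensor, no_grad

rng = np.random.default_rng(0)
d_z, T = 4, 6
flow = PriorFlow(
    d_z, n_steps=3, n_heads_flow=2, d_model=16, n_heads_attn=2,
    ffn_mult=2, cond_layers=1, max_len=24, rng=rng,
)
# randomize so the flow is not the identity
for step in flow.steps:
    step.actnorm.scale.data = rng.uniform(0.5, 1.5, d_z)
    step.actnorm.initialized = True
    step.coupling.net.out_proj.weight.data = (
        0.4 * rng.standard_normal(step.coupling.net.out_proj.weight.shape)
    )

x = Tensor(rng.standard_normal((1, 8, 16)))  # a frozen "spectrum embedding"
x_mask = np.ones((1, 8), dtype=bool)
token_mask = np.ones((1, T), dtype=bool)

z = Tensor(rng.standard_normal((1, T, d_z)))
with no_grad():
    u, logdet = flow.forward(z, token_mask, x, x_mask)
    z_back = flow.inverse(u, token_mask, x, x_mask)
    log_p = flow.log_prob(z, token_mask, x, x_mask)

print(f"round-trip max |z - f^-1(f(z))| = {np.abs(z.data - z_back.data).max():.2e}")
print(f"log|det J| = {logdet.data[0]:+.4f}")
print(f"log p(z|x) = {log_p.data[0]:+.4f}")
print("\nSamples from the conditional prior at three noise scales:")
for scale in (0.1, 1.0, 3.0):
    s = flow.sample(x, x_mask, token_mask, np.random.default_rng(1), noise_scale=scale)
    print(f"  noise_scale={scale:>3}: latent std {s.data.std():.3f}")
print(
    "\nThe round-trip error is float precision, the log-determinant is exact\n"
    "(analytic per layer), and larger base noise widens the latent samples."
)
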