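"""Measured-data pathway: noise, filtering, numerical differentiation.

Emulates a motion-capture recording by sampling the sinusoidal gait at
200 Hz and adding 1 mm Gaussian position noise, then runs the measured-data
pipeline: zero-phase 6/10 Hz low-pass filtering interleaved with
central-difference differentiation, step detection from the height extrema,
inverse dynamics and per-step cost of transport.
"""

from comwalk import (
    GaitParameters,
    SyntheticGaitSpec,
    add_noise,
    analyze_synthetic,
    analyze_trajectory,
    gen_sinusoidal,
)

params = GaitParameters(m=94.0)
gait = gen_sinusoidal(
    SyntheticGaitSpec(kind="sinusoidal", n_steps=4, sample_rate=200.0)
)

ref = analyze_synthetic(gait, params).mean_cost_of_transport
print(f"noise-free C (exact derivatives): {ref:.4f}")

for seed in range(3):
    noisy = add_noise(gait.trajectory, sigma=1e-3, seed=seed)
    res = analyze_trajectory(noisy, params, filter_on=True)
    dev = 100 * (res.mean_cost_of_transport / ref - 1)
    print(
        f"seed {seed}: {len(res.segments)} steps detected, "
        f"mean d = {res.stats['step_length_m_mean']:.3f} m, "
        f"C = {res.mean_cost_of_transport:.4f} ({dev:+.1f}% vs noise-free)"
    )

print(
    "\nWith realistic marker noise the filtered pipeline recovers the"
    "\nnoise-free cost of transport to within a few percent."
)
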