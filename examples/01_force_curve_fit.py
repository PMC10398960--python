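"""Fit one AFM force-distance curve with the Hertz sphere model.

Simulates a single approach curve on tissue of known stiffness
(300 Pa) with baseline tilt and sensor noise, then runs the full
chain: baseline correction, contact-point detection, conversion to
force-indentation, and the restricted (≤7 μm) Hertz fit.
"""

from hippomech import analyze_curve
from hippomech.synthgen import CurveGenParams, simulate_force_curve

params = CurveGenParams(
    elastic_modulus=300.0,  # Pa, "ground truth" stiffness of the sample
    contact_point=20.0,     # μm piezo height where the bead touches tissue
    noise_sd=0.05,          # nN of force noise on the deflection signal
    baseline_slope=0.01,    # nN/μm optical-interference tilt before contact
    seed=7,
)
curve = simulate_force_curve(params)
result = analyze_curve(curve)

print(f"samples in curve:        {curve.n_samples}")
print(f"fitted Young's modulus:  {result.elastic_modulus:.1f} Pa (true 300.0)")
print(f"estimated contact point: {result.contact_point:.3f} μm (true 20.000)")
print(f"max fitted indentation:  {result.fit_max_indentation:.2f} μm (cap 7)")
print(f"contact radius:          {result.contact_radius:.2f} μm (< bead 12.5)")
print(f"rms residual:            {result.rms_residual:.4f} nN  [{result.quality_flag}]")
# The fitted modulus should land within a few percent of 300 Pa; the
# contact radius stays below the 12.5 μm bead radius, which is the
# validity condition of the sphere-on-half-space Hertz model.
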