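"""Centralised unit conventions and conversion factors.

All internal quantities use a single convention:

=================  =======
quantity           unit
=================  =======
piezo height z     μm
deflection d       μm
indentation δ      μm
bead radius R      μm
force F            nN
elastic modulus E  Pa
spring constant k  N/m
=================  =======

Mixing these raises two classic pitfalls that this module removes:

* ``E[Pa] * sqrt(R[μm]) * δ[μm]^{3/2}`` has units Pa·μm² = 1e-12 N
  = 1e-3 nN, hence :data:`NN_PER_PA_UM2`.
* ``k[N/m] * d[μm]`` has units 1e-6 N = 1e3 nN per (N/m·μm), hence
  :data:`NN_PER_NPM_UM`.
"""

#: nN per Pa·μm² — converts the raw Hertz expression to nanonewtons.
NN_PER_PA_UM2 = 1.0e-3

#: nN per (N/m × μm) — converts spring constant × deflection to force.
NN_PER_NPM_UM = 1.0e3


def force_from_deflection(deflection_um: float, spring_constant_npm: float) -> float:
    """Hooke's law F = k·d with the package unit convention (returns nN)."""
    return spring_constant_npm * deflection_um * NN_PER_NPM_UM


def deflection_from_force(force_nn: float, spring_constant_npm: float) -> float:
    """Inverse Hooke's law d = F/k (returns μm)."""
    return force_nn / (spring_constant_npm * NN_PER_NPM_UM)
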