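"""Reduced-unit conventions used throughout the package.

All energies are measured in the reduced energy unit ``epsilon``, lengths in
Angstrom, and Boltzmann's constant is 1, so temperature carries units of
epsilon/k_B.  The default simulation temperature is T = 0.5 epsilon/k_B, which
makes k_B*T = 0.5 epsilon the natural conversion between "epsilon" and "k_BT"
scales.  One reduced time unit corresponds to roughly 1 ns of effective
dynamics for this class of model; the constant below is a labeling aid only
and never enters any computation.
"""

#: default reduced simulation temperature (epsilon / k_B)
TEMPERATURE: float = 0.5

#: k_B * T at the default temperature, in epsilon
KT: float = 0.5

#: labeling constant: approximate physical time per reduced time unit (ns)
NS_PER_REDUCED_TIME: float = 1.0


def kt(temperature: float = TEMPERATURE) -> float:
    """Thermal energy k_B*T in epsilon for a reduced temperature."""
    return float(temperature)
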