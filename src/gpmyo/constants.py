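"""Physical constants and unit conventions.

Unit system used throughout the package:

* time            ms
* voltage         mV
* concentration   mM
* current density uA/uF (outward positive)
* volume          uL (1 pL = 1e-6 uL)

All fluxes are referenced to the volume of the compartment whose balance they
enter unless stated otherwise; conversion factors live in the assembled cell
model so that each is applied at exactly one documented point.
"""

FARADAY = 96.485          # C / mmol
R_GAS = 8.314             # J / (mol K)
TEMP = 310.0              # K
RT_OVER_F = 26.712338     # mV, R*T/F at 310 K
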