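"""Unit conventions and conversion constants.

All public interfaces use a single NEURON-like system of units:

=====================  ==========  ==========================================
quantity               unit        notes
=====================  ==========  ==========================================
length                 um          geometry, distances, probe positions
membrane potential     mV          Vm, Vin, Vout
time                   ms
current                nA          injected, axial, membrane, synaptic
specific capacitance   uF/cm^2     ``Section.cm``
axial resistivity      ohm*cm      ``Section.ra``
axial resistance       Mohm        mV / Mohm = nA
conductance (lumped)   uS          uS * mV = nA
synaptic conductance   nS          per spec of synapse interfaces
specific current       mA/cm^2     membrane-model output (ionic current/area)
specific conductance   mS/cm^2     membrane-model parameters
extracellular sigma    S/m         conductivity of the medium
=====================  ==========  ==========================================

Derived conversion factors (kept here so no module hand-rolls its own):

* axial resistance of a cylinder piece, ``R [Mohm] = ra * L / (pi r^2) *
  OHM_CM_UM_TO_MOHM`` with ``ra`` in ohm*cm and lengths in um.
* lumped capacitance ``C [nF] = cm * area * UF_CM2_UM2_TO_NF``; then
  ``C [nF] * dV/dt [mV/ms] = I [nA]`` with no further factor.
* specific ionic current to lumped current,
  ``I [nA] = i_spec [mA/cm^2] * area [um^2] * MA_CM2_UM2_TO_NA``.
* extracellular potential of a point source,
  ``V [mV] = I [nA] / (4 pi sigma [S/m] * R [um])`` — the 1e-9/1e-6 factors
  cancel to exactly 1e-3 V per (nA / (S/m * um)), i.e. unity in mV.
"""

import numpy as np

#: ohm*cm * um / um^2 -> Mohm  (1e4 ohm*um per ohm*cm, 1e-6 Mohm per ohm)
OHM_CM_UM_TO_MOHM = 1e-2

#: uF/cm^2 * um^2 -> nF  (1e-8 cm^2 per um^2, 1e3 nF per uF)
UF_CM2_UM2_TO_NF = 1e-5

#: mA/cm^2 * um^2 -> nA  (1e-8 cm^2 per um^2, 1e6 nA per mA)
MA_CM2_UM2_TO_NA = 1e-2

#: mS/cm^2 * um^2 -> uS
MS_CM2_UM2_TO_US = 1e-5

#: nS * mV -> nA
NS_MV_TO_NA = 1e-3

#: point-source prefactor: V[mV] = POINT_SOURCE_MV * I[nA] / (sigma[S/m] * R[um])
POINT_SOURCE_MV = 1.0 / (4.0 * np.pi)
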