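"""Published landscape-topography measurements for five homodimers.

Reference values from reported cluster-scale replica-exchange studies of
five 3-state homodimers (PDB: 1cop, 1lmb, 1lfb, 3mus, 1xso): interfacial
binding landscapes quantified with the monomers rigid ("independent"
binding) and fully flexible ("effective" binding), and monomeric folding
landscapes with and without the dimeric environment.  Energies and
temperatures are in reduced units; binding times are relative (only their
ratios are meaningful).  These numbers serve as inputs for the closed-form
topography operations and as the internal-consistency oracle: Lambda, Tg
and Tf/Tg recomputed from the tabulated gap, roughness, entropy and Tf
must agree with the tabulated values to the printed rounding.
"""

from __future__ import annotations

import numpy as np
from scipy.constants import Avogadro

PDB_IDS = ("1cop", "1lmb", "1lfb", "3mus", "1xso")

#: interfacial-binding landscapes; per system: rigid ("ind") vs flexible
#: ("eff") monomers. binding_time is in relative units.
BINDING = {
    "1cop": {
        "ind": dict(delta_E=57.56, Delta_E=11.01, S=42.12, Tf=1.95, Tg=1.20,
                    Tf_over_Tg=1.62, binding_time=9.92, Lambda=0.56),
        "eff": dict(delta_E=57.02, Delta_E=5.37, S=74.58, Tf=0.97, Tg=0.44,
                    Tf_over_Tg=2.20, binding_time=7.08, Lambda=0.86),
    },
    "1lmb": {
        "ind": dict(delta_E=48.89, Delta_E=9.92, S=40.67, Tf=1.59, Tg=1.10,
                    Tf_over_Tg=1.45, binding_time=9.70, Lambda=0.54),
        "eff": dict(delta_E=48.03, Delta_E=5.77, S=64.00, Tf=0.92, Tg=0.51,
                    Tf_over_Tg=1.80, binding_time=7.64, Lambda=0.73),
    },
    "1lfb": {
        "ind": dict(delta_E=49.70, Delta_E=8.09, S=43.27, Tf=1.62, Tg=0.87,
                    Tf_over_Tg=1.86, binding_time=9.44, Lambda=0.66),
        "eff": dict(delta_E=49.19, Delta_E=4.89, S=67.79, Tf=0.98, Tg=0.42,
                    Tf_over_Tg=2.33, binding_time=7.50, Lambda=0.86),
    },
    "3mus": {
        "ind": dict(delta_E=40.63, Delta_E=7.00, S=41.36, Tf=1.39, Tg=0.77,
                    Tf_over_Tg=1.80, binding_time=7.92, Lambda=0.63),
        "eff": dict(delta_E=40.41, Delta_E=5.58, S=53.47, Tf=0.97, Tg=0.54,
                    Tf_over_Tg=1.79, binding_time=7.08, Lambda=0.69),
    },
    "1xso": {
        "ind": dict(delta_E=59.31, Delta_E=8.74, S=47.11, Tf=1.66, Tg=0.90,
                    Tf_over_Tg=1.84, binding_time=7.64, Lambda=0.69),
        "eff": dict(delta_E=59.35, Delta_E=7.57, S=62.03, Tf=1.21, Tg=0.68,
                    Tf_over_Tg=1.78, binding_time=9.21, Lambda=0.70),
    },
}

#: monomeric-folding landscapes; isolated ("ind") vs dimeric ("eff").
FOLDING = {
    "1cop": {
        "ind": dict(delta_E=205.95, Delta_E=9.34, S=189.35, Tf=0.98, Tg=0.48,
                    Tf_over_Tg=2.04, Lambda=1.13),
        "eff": dict(delta_E=205.75, Delta_E=9.06, S=185.92, Tf=1.00, Tg=0.47,
                    Tf_over_Tg=2.13, Lambda=1.17),
    },
    "1lmb": {
        "ind": dict(delta_E=303.79, Delta_E=11.44, S=261.70, Tf=1.06, Tg=0.50,
                    Tf_over_Tg=2.12, Lambda=1.16),
        "eff": dict(delta_E=304.44, Delta_E=11.44, S=261.57, Tf=1.06, Tg=0.50,
                    Tf_over_Tg=2.12, Lambda=1.16),
    },
    "1lfb": {
        "ind": dict(delta_E=248.46, Delta_E=10.12, S=222.12, Tf=0.99, Tg=0.48,
                    Tf_over_Tg=2.06, Lambda=1.16),
        "eff": dict(delta_E=246.06, Delta_E=9.72, S=223.36, Tf=1.00, Tg=0.46,
                    Tf_over_Tg=2.17, Lambda=1.19),
    },
    "3mus": {
        "ind": dict(delta_E=285.31, Delta_E=10.88, S=257.11, Tf=1.02, Tg=0.48,
                    Tf_over_Tg=2.12, Lambda=1.15),
        "eff": dict(delta_E=288.39, Delta_E=10.87, S=256.32, Tf=1.02, Tg=0.48,
                    Tf_over_Tg=2.12, Lambda=1.17),
    },
    "1xso": {
        "ind": dict(delta_E=626.12, Delta_E=17.41, S=501.29, Tf=1.22, Tg=0.55,
                    Tf_over_Tg=2.22, Lambda=1.13),
        "eff": dict(delta_E=628.95, Delta_E=17.29, S=494.16, Tf=1.24, Tg=0.55,
                    Tf_over_Tg=2.25, Lambda=1.15),
    },
}

#: interfacial flexibility rho of each homodimer (fraction of residues
#: with both inter- and intra-chain native contacts).
RHO = {"1cop": 0.18, "1lmb": 0.17, "1lfb": 0.16, "3mus": 0.12, "1xso": 0.09}


def effective_concentration(r0_nm: float = 6.0, n_molecules: int = 2) -> float:
    """Effective molar concentration (mM) of ``n_molecules`` confined to a
    sphere of radius ``r0_nm`` — the concentration set by the COM
    confinement used to enhance binding sampling."""
    volume_l = (4.0 / 3.0) * np.pi * r0_nm**3 * 1e-24  # nm^3 -> litres
    return n_molecules / (Avogadro * volume_l) * 1e3      # mol/l -> mM
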