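"""Published μ-opioid receptor binding constants used as reference inputs.

Radioligand-derived equilibrium and kinetic constants for three nitazenes
(proto-, eto-, etodesnitazene), two reference agonists (fentanyl, carfentanil)
and two reversal agents (naloxone, nalmefene), as reported in the literature.
These serve as inputs for fold-ratio comparisons and as ground-truth presets
for the synthetic generators; they are not fitted by this package.

Fields per compound (missing entries are None):

- ``Kd_nM`` / ``Kd_se``: equilibrium dissociation constant from saturation binding
- ``kon_nM_min`` / ``kon_se``: association rate constant (nM⁻¹ min⁻¹)
- ``t_half_min`` / ``t_half_se``: dissociation half-life (min, 10 nM naloxone)
- ``calc_t_half_s`` / ``calc_t_half_se``: half-life from biased-simulation
  Poisson fitting (s)
- ``Ki_naloxone_nM``, ``Ki_nalmefene_nM`` (+ ``_se``): competitive-displacement
  inhibitor constants of the two reversal agents
"""

PUBLISHED_KINETICS = {
    "protonitazene": {
        "Kd_nM": 0.164, "Kd_se": 0.060,
        "kon_nM_min": 0.93, "kon_se": 0.33,
        "t_half_min": 34.5, "t_half_se": 2.7,
        "calc_t_half_s": 18.3, "calc_t_half_se": 0.3,
        "Ki_naloxone_nM": 16.0, "Ki_naloxone_se": 3.9,
        "Ki_nalmefene_nM": 1.93, "Ki_nalmefene_se": 0.25,
    },
    "etonitazene": {
        "Kd_nM": 0.082, "Kd_se": 0.002,
        "kon_nM_min": 1.12, "kon_se": 0.13,
        "t_half_min": 14.2, "t_half_se": 0.6,
        "calc_t_half_s": 0.26, "calc_t_half_se": 0.02,
        "Ki_naloxone_nM": 11.8, "Ki_naloxone_se": 2.5,
        "Ki_nalmefene_nM": 1.70, "Ki_nalmefene_se": 0.24,
    },
    "etodesnitazene": {
        "Kd_nM": 0.473, "Kd_se": 0.047,
        "kon_nM_min": 0.69, "kon_se": 0.14,
        "t_half_min": 8.3, "t_half_se": 1.1,
        "calc_t_half_s": 0.0144, "calc_t_half_se": 0.0006,
        "Ki_naloxone_nM": 4.2, "Ki_naloxone_se": 1.2,
        "Ki_nalmefene_nM": 1.12, "Ki_nalmefene_se": 0.32,
    },
    "fentanyl": {
        "Kd_nM": 0.602, "Kd_se": 0.063,
        "kon_nM_min": 0.68, "kon_se": 0.14,
        "t_half_min": 4.27, "t_half_se": 0.53,
        "calc_t_half_s": None, "calc_t_half_se": None,
        "Ki_naloxone_nM": 2.1, "Ki_naloxone_se": 0.2,
        "Ki_nalmefene_nM": 0.27, "Ki_nalmefene_se": 0.07,
    },
    "carfentanil": {
        "Kd_nM": 0.049, "Kd_se": 0.004,
        "kon_nM_min": 0.67, "kon_se": 0.04,
        "t_half_min": 22.9, "t_half_se": 1.8,
        "calc_t_half_s": None, "calc_t_half_se": None,
        "Ki_naloxone_nM": 4.7, "Ki_naloxone_se": 0.7,
        "Ki_nalmefene_nM": 0.49, "Ki_nalmefene_se": 0.05,
    },
    "naloxone": {
        "Kd_nM": 0.711, "Kd_se": 0.077,
        "kon_nM_min": 3.96, "kon_se": 0.67,
        "t_half_min": None, "t_half_se": None,
        "calc_t_half_s": None, "calc_t_half_se": None,
        "Ki_naloxone_nM": None, "Ki_naloxone_se": None,
        "Ki_nalmefene_nM": None, "Ki_nalmefene_se": None,
    },
    "nalmefene": {
        "Kd_nM": 1.490, "Kd_se": 0.790,
        "kon_nM_min": 2.43, "kon_se": 0.30,
        "t_half_min": None, "t_half_se": None,
        "calc_t_half_s": None, "calc_t_half_se": None,
        "Ki_naloxone_nM": None, "Ki_naloxone_se": None,
        "Ki_nalmefene_nM": None, "Ki_nalmefene_se": None,
    },
}

#: Dissociation half-lives (min) measured at 10 μM unlabeled naloxone — a
#: saturating antagonist concentration used to confirm the rank order.
T_HALF_MIN_AT_10UM_NALOXONE = {
    "protonitazene": 23.5,
    "fentanyl": 3.7,
    "carfentanil": 19.7,
}

NITAZENES = ("protonitazene", "etonitazene", "etodesnitazene")
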