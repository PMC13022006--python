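"""Trophic positions and nutritional modes from amino-acid δ¹⁵N.

Builds a four-sample seston table, one per nutritional-mode archetype,
computes TP_Glu and TP_Ala, and classifies each sample.  The TP pair reads
as: TP_Glu ≈ 1.5 flags osmotrophy, TP_Ala ≥ ~1.5 flags phagotrophy; both
together are the mixoplankton signature.
"""

import pandas as pd

from plumetroph import classify_profiles, endmember_overlay

# δ15N (permil vs air); Phe baseline 5 permil, trophic AAs placed on the
# TP 1.0 / 1.5 trophoclines
samples = pd.DataFrame(
    [
        {"sample_id": "pure_autotroph", "d15n_phe": 5.0, "d15n_glu": 8.4, "d15n_ala": 8.2},
        {"sample_id": "osmotroph", "d15n_phe": 5.0, "d15n_glu": 12.2, "d15n_ala": 8.2},
        {"sample_id": "phagotroph", "d15n_phe": 5.0, "d15n_glu": 8.4, "d15n_ala": 11.05},
        {"sample_id": "mixoplankton", "d15n_phe": 5.0, "d15n_glu": 12.2, "d15n_ala": 11.05},
    ]
)

calls = classify_profiles(samples)
print(calls[["sample_id", "tp_glu", "tp_ala", "mode"]].to_string(index=False))

print("\nNearest trophocline per sample and amino acid:")
overlay = endmember_overlay(samples)
print(overlay.to_string(index=False))
print(
    "\nEach sample sits exactly on its generating trophoclines "
    "(distance 0 permil), so the four archetype modes are recovered."
)
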