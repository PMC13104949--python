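"""Fold-ratio comparisons between published μOR binding constants.

How much more reversal agent does displacing a nitazene take, compared with
carfentanil? Ratios of the literature Ki values (naloxone and nalmefene
against each opioid) answer that directly: a ratio of 3.4 means displacement
needs ~3.4x the antagonist concentration.
"""

from bindkin.pipeline import compare_compounds
from bindkin.reference import NITAZENES, PUBLISHED_KINETICS

table = compare_compounds(PUBLISHED_KINETICS, "carfentanil",
                          fields=("Ki_naloxone_nM", "Ki_nalmefene_nM"))
print("fold ratios vs carfentanil (Ki of the reversal agent):")
print(f"{'compound':18s} {'naloxone':>9s} {'nalmefene':>10s}")
for name in (*NITAZENES, "fentanyl", "carfentanil"):
    row = table[name]
    print(f"{name:18s} {row['Ki_naloxone_nM']:9.1f} "
          f"{row['Ki_nalmefene_nM']:10.1f}")

kd_ratio = (PUBLISHED_KINETICS['nalmefene']['Kd_nM']
            / PUBLISHED_KINETICS['naloxone']['Kd_nM'])
print(f"\nnalmefene/naloxone Kd ratio: {kd_ratio:.1f} "
      "(nalmefene binds about twofold weaker)")
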