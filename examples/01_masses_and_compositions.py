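"""Glycan composition masses and composition search.

Computes the sodiated monoisotopic m/z of a few derivatized N-glycan
compositions and searches for compositions matching an observed peak.
"""

import glycotrait as gt

print("Sodiated monoisotopic m/z ([M+Na]+):")
for comp in ("H5N2", "H5N4F1", "H5N4L1E1", "H7N6L4F1"):
    print(f"  {comp:10s} {gt.composition_mass(comp):10.4f}")
# These are the masses at which each composition appears in a positive-mode
# MALDI-TOF spectrum after linkage-specific sialic acid derivatization
# (L = alpha2,3-linked NeuAc lactone, E = alpha2,6-linked ethyl ester).

print("\nFirst three isotopologue fractions of H5N4F1L1E1:")
print(" ", gt.isotopic_pattern("H5N4F1L1E1", k=3).round(4))
# The targeted extractor integrates only these three peaks and divides by
# their summed fraction to recover the full-envelope area.

print("\nCompositions within 10 ppm of m/z 2255.793:")
for comp in gt.enumerate_compositions(2255.793, tol_ppm=10):
    print(f"  {comp}  ({gt.composition_mass(comp):.4f})")
# A unique hit means the peak can be assigned by mass alone at this accuracy.
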