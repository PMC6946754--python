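"""Sum-formula annotation of PTR-ToF peaks.

Computes theoretical cation masses for the ions that dominate an
isoprene-emitting leaf headspace and annotates a measured centroid by
exhaustive search over a bounded CHON lattice.
"""

from ptrscreen import annotate, monoisotopic_mz

print("Theoretical m/z of common product ions (Th):")
for formula in ["H3O+", "H3O18+", "C5H9+", "C5H9O+", "C10H17+"]:
    print(f"  {formula:8s} -> {monoisotopic_mz(formula):9.4f}")

# A measured centroid near the isoprene product ion: with ~1 mTh mass
# accuracy the sum formula is unambiguous inside realistic element bounds.
observed = 69.0683  # measured centroid, 1.6 mTh from theory
candidates = annotate(observed, tolerance=0.005,
                      element_bounds={"C": 10, "H": 20, "O": 3, "N": 2})
print(f"\nCandidates within 5 mTh of the measured centroid {observed}:")
for c in candidates[:5]:
    print(f"  {c.formula.hill():10s} theory {c.theoretical_mz:.4f}  "
          f"delta {1000 * c.delta_mz:+.1f} mTh")
print("\nThe first candidate is the protonated-isoprene ion C5H9+: the")
print("sub-2-mTh offset is the measured centroid's error, not ambiguity.")
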