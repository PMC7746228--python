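"""TM-score fold comparison on idealized seven-helix bundles.

Builds an antiparallel seven-helix bundle (the receptor family's packing
arrangement), perturbs copies with increasing coordinate noise, and
scores each against the clean bundle.  TM-scores >= 0.5 indicate the same
fold, <= 0.30 only random similarity; the self-comparison is exactly 1.00.
"""

from grlscreen.structcompare import compare_structures
from grlscreen.synthetic_data import make_bundle

base, _ = make_bundle(seed=0)
print(f"bundle: {len(base)} residues, 7 antiparallel helices")
print(f"{'noise sd (A)':>12s} {'TM-score':>9s} {'RMSD (A)':>9s}  class")
for sigma in (0.0, 0.5, 2.0, 5.0, 10.0):
    noisy, _ = make_bundle(seed=0, noise_sigma=sigma)
    comp = compare_structures(base, noisy)
    print(f"{sigma:12.1f} {comp.tm_score:9.3f} {comp.rmsd:9.2f}  {comp.classification}")

print("\nthe score decays monotonically with noise; 0.5 A of noise leaves the"
      "\nfold intact (same_fold) while 10 A reduces it to random similarity")
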