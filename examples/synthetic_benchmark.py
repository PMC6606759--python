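"""Recall benchmark on a seeded synthetic LC-MS feature list.

Samples 200 species from a four-metal sub-catalog, perturbs their [M+H]
m/z by 1 ppm Gaussian jitter (a realistic high-resolution instrument error),
adds 50 decoy masses placed away from every theoretical value, and measures
how the annotator performs at 5 ppm tolerance.  Recall is the fraction of
true features whose generating species is recovered; every match on a decoy
would be a false annotation.
"""

from pycdb import (
    EnumerationConfig,
    annotate_masses,
    enumerate_catalog,
    evaluate_annotation,
    generate_query_set,
)

catalog = enumerate_catalog(EnumerationConfig(metals=("Cd", "Hg", "Pb", "Zn")))
qs = generate_query_set(
    catalog, n_true=200, n_decoys=50, jitter_ppm_sd=1.0, adducts=("M+H",), seed=7
)
matches = annotate_masses(
    list(qs.queries), catalog, adducts=["M+H"], tolerance_ppm=5.0
)
scores = evaluate_annotation(qs, matches)

print(f"catalog size            : {len(catalog)}")
print(f"queries                 : {qs.n_true} true + {qs.n_decoys} decoys")
print(f"matches emitted         : {len(matches)}")
print(f"recall                  : {scores['recall']:.3f}")
print(f"false annotations       : {int(scores['false_annotation_count'])}")
print("(recall ~1.0 and zero decoy hits are expected: 1-ppm errors lie well")
print(" inside the 5-ppm window, and decoys are guard-banded away from it)")
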