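"""Annotate a small experimental m/z list against the catalog.

The query values below are measured LC-MS features (including the onion
feature 538.1254 and a Zn-complex mass); each is matched against every
catalog species as an [M+H] adduct within 10 ppm.  The ppm error is the
signed relative deviation of the measured from the theoretical m/z — values
within a few ppm are what a well-calibrated Orbitrap-class instrument
delivers, so larger deviations would warrant suspicion.
"""

from pycdb import annotate_masses, enumerate_catalog

catalog = enumerate_catalog()
queries = [538.1254, 540.1437, 602.0560, 1004.2436, 1416.1556]

matches = annotate_masses(queries, catalog, adducts=["M+H"], tolerance_ppm=10.0)
print(f"{len(matches)} matches for {len(queries)} queries at 10 ppm, [M+H]:")
for m in matches:
    print(
        f"  {m.query_mz:10.4f} -> {m.species.name:18s} "
        f"{m.species.formula_str:24s} theo {m.theoretical_mz:10.4f} "
        f"({m.ppm_error:+.1f} ppm)"
    )
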