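# pycdb — a generative phytochelatin database and accurate-mass annotator

Phytochelatins (PyCs) are glutathione-derived plant peptides,
(γ-Glu-Cys)<sub>n</sub>-X with n = 2–11 repeats and a variable C-terminal
residue X ∈ {Gly, Ala/β-Ala, Gln, Ser, Glu, none}, whose cysteine thiols
chelate metals of nutritional and toxicological importance (Zn, Cu, Fe, Se,
Mn; Cd, Pb, Hg, Ni, Co, Ag; plus Ca and Mg). Because PyCs vary in length,
terminal residue, oxidation state (up to five intramolecular disulfide
bonds) and bound-metal content, the space of observable species is large —
far too large to curate by hand, yet fully determined by a small set of
construction rules. `pycdb` generates that space deterministically and lets
you search it with high-resolution mass-spectrometry data.

**Who it is for:** metabolomics and trace-metal researchers annotating
LC-MS feature tables (m/z lists) from plants and plant-derived foods, and
anyone needing exact monoisotopic masses of PyC–metal complexes.

## The model

Every species is an elemental formula built by arithmetic on multisets of
atoms:

- **Backbone.** n condensed γ-Glu-Cys units contribute
  n·C₈H₁₂N₂O₄S + H₂O; the terminal residue adds its delta (e.g. Gly:
  +C₂H₃NO). Ala and β-Ala are elementally identical and share one record.
- **Disulfides.** Each of m S–S bonds removes 2 H and consumes two
  cysteine thiols; m ≤ min(⌊n/2⌋, 5).
- **Metal binding.** A divalent ion (Cd, Co, Cu, Fe, Pb, Mn, Hg, Ni, Zn,
  Ca, Mg — and Se, bound as a formally divalent selenotrisulfide
  –S–Se–S–) displaces two thiol protons (−2 H); monovalent Ag displaces one
  (−1 H). Every bound ion requires **two free thiols**, so a complex forms
  only when n − 2m ≥ 2 per ion. One- and two-metal complexes are generated
  over all 13 metals (91 unordered pairs).
- **Bridges.** Each two-metal complex additionally occurs with a bridging
  sulfido (+S), disulfido (+2 S) or selenido (+Se) atom, by analogy with
  iron–sulfur clusters.

Monoisotopic masses are sums of most-abundant-isotope exact masses
(¹H, ¹²C, ¹⁴N, ¹⁶O, ³²S, ⁸⁰Se, ¹¹⁴Cd, ²⁰²Hg, …) from a versioned table in
`src/pycdb/data/isotope_masses.csv`. Adduct m/z is
(M + m<sub>adduct</sub>)/z with the proton (1.00727646 Da) as charge
carrier; a query matches when |10⁶·(obs − theo)/theo| ≤ the ppm tolerance.
An optional NOPS filter discards formulas with implausible N/C, O/C, P/C,
S/C ratios.

With the default configuration the catalog contains exactly **240**
metal-free PyCs, **2 340** one-metal and **43 680** two-metal complexes —
**46 260** unique elemental formulas.

## Worked example

```python
from pycdb import enumerate_catalog, annotate_masses

catalog = enumerate_catalog()          # 46 260 species, ~2 s
matches = annotate_masses([538.1254, 602.0560], catalog,
                          adducts=["M+H"], tolerance_ppm=10.0)
for m in matches:
    print(f"{m.query_mz:9.4f} -> {m.species.name:15s} "
          f"{m.species.formula_str:16s} {m.theoretical_mz:9.4f} {m.ppm_error:+.1f} ppm")
```

prints

```
 538.1254 -> (S-S)PyC2-Gly   C18H27N5O10S2     538.1272 -3.4 ppm
 602.0560 -> PyC2-Gly-Zn     C18H27N5O10S2Zn   602.0564 -0.6 ppm
```

i.e. the measured feature 538.1254 is the protonated single-disulfide form
of PyC₂-Gly within 3.4 ppm, and 602.0560 is the one-zinc complex of
PyC₂-Gly within 0.6 ppm — both comfortably inside the error of a modern
high-resolution instrument. Longer scripts, one per capability, live in
`examples/` (`build_catalog.py`, `annotate_features.py`,
`synthetic_benchmark.py`).

The same operations are available from the shell:

```sh
pycdb build -o pycdb_catalog.csv
pycdb annotate -i features.txt -o matches.csv --ppm 5 --adducts M+H
pycdb fixtures -o synthetic.txt --n-true 100 --n-decoys 50 --seed 1
```

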