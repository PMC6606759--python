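# Methods

## Species model

A phytochelatin species is identified by the tuple (terminal residue,
repeat count n, disulfide count m, bound-metal multiset, bridge type) and
represented by its elemental formula — an integer multiset over
{C, H, N, O, S, Se} ∪ metal symbols. All construction is formula
arithmetic:

```
formula(terminal, n, m, metals, bridge)
  = n·C8H12N2O4S + H2O + Δ(terminal)
    − 2m·H                         (disulfide oxidation)
    − Σ_ions h_loss(ion)·H + ion   (thiolate metal binding)
    + Δ(bridge)                    (S, 2S or Se; two-metal only)
```

with Δ(Gly) = C₂H₃NO, Δ(Ala/β-Ala) = C₃H₅NO, Δ(none) = ∅,
Δ(Gln) = C₅H₈N₂O₂, Δ(Ser) = C₃H₅NO₂, Δ(Glu) = C₅H₇NO₃. `h_loss` is 2 for
the divalent class and 1 for Ag. The assumptions baked in:

- Metals bind exclusively through cysteine thiolates; O- and N-coordination
  is not modelled. Each bound ion engages exactly two thiols, so a species
  with f = n − 2m free thiols holds at most ⌊f/2⌋ ions; we enumerate up to
  two. The two-thiols-per-ion rule is applied uniformly to every metal
  class, including monovalent Ag and Se — this uniform rule is what closes
  the catalog arithmetic exactly (30 one-metal and 20 two-metal scaffolds
  per terminal family; see below).
- Se is treated as formally divalent (−2 H), binding two thiolates as the
  selenotrisulfide –S–Se–S–; the "(2−)" description of selenide leads to
  identical mass arithmetic either way.
- Bridged forms are exactly {+S, +2S, +Se} on two-metal complexes; no
  combined S+Se bridge and no diselenido form is generated.
- Coordination geometry, binding affinity and kinetics are out of scope:
  the catalog enumerates elementally distinct species, not structures.

### Count structure (closed form)

Per terminal family: Σₙ₌₂..₁₁ (min(⌊n/2⌋,5)+1) = 40 metal-free scaffolds;
30 scaffolds retain ≥ 2 free thiols (one-metal capable) and 20 retain ≥ 4
(two-metal capable). Hence 6×40 = 240 metal-free species,
6×30×13 = 2 340 one-metal, and 6×20×91×4 = 43 680 two-metal entries
(91 unordered metal pairs with repetition, 4 bridge forms), totalling
46 260. The test suite checks the enumerator against an independent
brute-force loop over all tuples, stratum by stratum, and asserts that all
46 260 formulas are pairwise distinct (the strata sums equal the unique
total, so there are no collisions).

## Masses and adducts

Monoisotopic mass is Σ count(e)·mass(e) over most-abundant-isotope exact
masses, shipped to 8 decimal places in `src/pycdb/data/isotope_masses.csv`
(current NIST values; the file is versioned with the package and never
fetched at runtime). Tests cross-check every entry against pyteomics'
independent NIST tables to < 5·10⁻⁵ Da — different NIST vintages agree far
below the 4-decimal reporting precision used for m/z. All internal
arithmetic is full double precision; rounding happens only at I/O.

Adduct m/z = (M + δ)/z. The charge carrier for protonated adducts is the
proton, 1.00727646 Da (not a hydrogen atom): the reference [M+H] values
only reproduce under this convention. Registry: M+H, M+2H, M+3H (searched
by default: M+H only in the CLI/RunConfig default, all three in the
library default), plus M+Na, M+K (atom minus electron) and M−H available
opt-in. Default tolerance is 5 ppm.

The ppm error is signed and uses the **theoretical** m/z as denominator:
10⁶·(obs − theo)/theo. Swapping the arguments changes |ppm| only at second
order (≲ tol²·10⁻⁶), which a property test documents. One reference
deviation (538.1254 vs the disulfide PyC₂-Gly) is only reproduced as
3.3 ppm when the theoretical value is first rounded to its printed 4
decimals (full precision gives 3.4 ppm); comparisons at printed precision
therefore round the theoretical value first, consistently with how such
tables are printed.

## NOPS filter

The optional plausibility filter bounds heteroatom-to-carbon ratios:
N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3, S/C ≤ 0.8 — the common-range heuristics
used in formula-filtering practice; the thresholds are configurable because
no single published cutoff is canonical. Ratios are computed on the
neutral formula; bound metals never enter any ratio; carbon-free formulas
fail closed. Every catalog species satisfies the default rule, so the
filter matters when the tool is pointed at mixed or third-party mass lists.

## Annotation semantics

Every (query, species, adduct) combination within tolerance is emitted —
no best-hit collapsing, ranking only by |ppm| within a query. Filters
narrow the searched catalog: a metal filter keeps species with at least one
bound metal, all of whose metals lie in the chosen subset (so metal-free
species are excluded whenever a metal filter is active); terminal and
n-range filters restrict the scaffold. Matching is implemented with a
sorted theoretical-m/z array and binary search, so annotating thousands of
queries against the full catalog is interactive.

## Synthetic query generator

`generate_query_set` emulates the m/z column of an LC-MS feature table:
n_true species drawn uniformly without replacement, each emitting one
adduct m/z perturbed multiplicatively by Normal(0, σ) ppm — instrument mass
error is relative, hence multiplicative jitter — plus decoys drawn
uniformly over the theoretical m/z range but rejected within
±(3σ + guard) ppm of any theoretical value (guard default 5 ppm). Decoys
are therefore unmatched by construction at tolerances up to the guard, and
any decoy match is a genuine false annotation. A catalog too dense for the
requested guard raises an error rather than silently degrading; the
benchmark in the tests uses a four-metal (Cd, Hg, Pb, Zn; 5 760-species)
sub-catalog, where guarded placement is comfortably feasible, with 200 true
queries, 50 decoys, 1 ppm jitter and 10 seeds.

What the generator does **not** emulate: retention time, intensity,
isotope envelopes, in-source fragments, multiply charged overlaps, or
correlated calibration drift. Passing recall ≈ 1.0 therefore shows the
matcher is correct and well-calibrated under its own error model, not that
real-data annotation is unambiguous — the worked examples show a single
m/z can legitimately match several species, and resolving those requires
orthogonal evidence (MS/MS, retention time, isotope patterns), which is
out of scope here.

## Numerical and design choices

- Catalog order is fixed: terminal family (Gly, Ala, none, Gln, Ser, Glu),
  n, m, metal count, alphabetical metal multiset, bridge (none, sulfido,
  disulfido, selenido). `write_catalog` is byte-deterministic (10-decimal
  masses, LF newlines), so rebuilt catalogs diff clean.
- Names follow the field's abbreviation grammar:
  `(S-S)k PyC{n}[-terminal][-metal][(bridge)]`, e.g. `(S-S)2PyC6-Gly`,
  `PyC4-Gly-Cd(2)(Se)`, `PyC4-Gly-CdZn`. The terminal residue is always
  printed (some literature labels omit `-Gly`); Ala species carry a
  β-Ala alias.
- Degenerate inputs: negative element counts, thiol-rule violations,
  bridges on non-two-metal species, out-of-range n or m, empty adduct
  lists, empty or non-numeric query files all raise informative errors
  rather than producing silent partial output.
- The curated reference set (`src/pycdb/data/reference_mz.csv`) stores each
  literature [M+H] value with its printed decimal count and is compared
  after rounding, not with a fixed epsilon. One literature label printed as
  the plain one-Hg PyC₄ complex carries a mass equal to the single-disulfide
  Hg complex (−4 H total); the fixture maps it to that species and keeps the
  original label in a `reported_as` column.

## Limitations

- No ≥3-metal complexes, no Mo/As, no K/Na complex forms, no
  selenocysteine substitution, no diselenido bridges.
- No confidence scoring, retention-time clustering or isotope-abundance
  checks; output is a flat match table.
- The catalog asserts elemental-formula uniqueness; if future rule
  extensions introduce collisions, catalog construction fails loudly and
  the indexing scheme would need a compound key.
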