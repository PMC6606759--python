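"""Regression fixtures and a seeded synthetic query generator.

Two complementary test surfaces live here.  :func:`worked_examples` loads a
curated set of phytochelatin [M+H] values reported in the mass-spectrometry
literature (stored at their printed decimal precision) and rebuilds each
species from its construction recipe, so the whole formula -> mass -> adduct
pipeline can be checked end to end.  :func:`generate_query_set` emulates an
LC-MS feature list: true queries are theoretical adduct m/z values of
catalog species perturbed by Gaussian ppm jitter (a multiplicative error, as
instrument mass error behaves), and decoy queries are placed uniformly over
the catalog's m/z range but away from every theoretical value, so any match
on a decoy is a guaranteed false annotation.

The synthetic set emulates mass positions only — no retention times,
intensities, isotope envelopes or in-source fragments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .annotate import Adduct, AnnotationMatch, adduct_mz, get_adduct
from .catalog import (
    PyCSpecies,
    SpeciesCatalog,
    apply_disulfides,
    base_species,
    bind_metals,
)

__all__ = [
    "SyntheticQuerySet",
    "WorkedExample",
    "evaluate_annotation",
    "generate_query_set",
    "predicted_mz",
    "worked_examples",
]


@dataclass(frozen=True)
class WorkedExample:
    """One literature-reported [M+H] value with its construction recipe."""

    name: str
    reported_as: str  # label as printed in the source (may omit the terminal)
    terminal: str
    n: int
    disulfides: int
    metals: tuple[str, ...]
    adduct: str
    expected_mz: str  # kept as text to preserve the printed decimal count

    @property
    def decimals(self) -> int:
        return len(self.expected_mz.partition(".")[2])

    @property
    def expected_value(self) -> float:
        return float(self.expected_mz)

    def build(self) -> PyCSpecies:
        """Construct the species from scratch via the catalog rules."""
        sp = apply_disulfides(base_species(self.terminal, self.n), self.disulfides)
        if self.metals:
            sp = bind_metals(sp, self.metals)
        return sp


def worked_examples() -> list[WorkedExample]:
    """The packaged reference set (>= 20 entries across all species classes)."""
    ref = resources.files("pycdb.data").joinpath("reference_mz.csv")
    out = []
    with ref.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            metals = tuple(m for m in (row["metal1"], row["metal2"]) if m)
            out.append(
                WorkedExample(
                    name=row["name"],
                    reported_as=row["reported_as"],
                    terminal=row["terminal"],
                    n=int(row["n"]),
                    disulfides=int(row["disulfides"]),
                    metals=metals,
                    adduct=row["adduct"],
                    expected_mz=row["expected_mz"],
                )
            )
    return out


def predicted_mz(example: WorkedExample) -> float:
    """Full-precision predicted adduct m/z for a worked example."""
    return adduct_mz(example.build().mass, example.adduct)


@dataclass(frozen=True)
class SyntheticQuerySet:
    """A seeded synthetic feature list with ground truth.

    ``queries`` holds the true queries first, then the decoys; ``truth`` maps
    query index -> (species name, adduct name) for exactly the true queries.
    """

    queries: tuple[float, ...]
    truth: dict[int, tuple[str, str]]
    n_true: int
    n_decoys: int
    jitter_ppm_sd: float
    seed: int

    def is_decoy(self, index: int) -> bool:
        return index >= self.n_true


def generate_query_set(
    catalog: SpeciesCatalog,
    n_true: int,
    n_decoys: int = 0,
    jitter_ppm_sd: float = 1.0,
    adducts: tuple[Adduct | str, ...] = ("M+H",),
    seed: int = 0,
    guard_ppm: float = 5.0,
    max_attempts_per_decoy: int = 10_000,
) -> SyntheticQuerySet:
    """Sample a reproducible synthetic query set from a catalog.

    *n_true* species are drawn uniformly without replacement; each emits the
    m/z of one uniformly chosen adduct, perturbed multiplicatively by
    ``Normal(0, jitter_ppm_sd)`` ppm.  Decoys are drawn uniformly over the
    theoretical m/z range and rejected while they fall within
    ``(3 * jitter_ppm_sd + guard_ppm)`` ppm of any theoretical m/z, so a
    decoy can never be a legitimate match at tolerances up to *guard_ppm*.
    A catalog too dense for the requested guard raises ``ValueError``.
    """
    if n_true > len(catalog):
        raise ValueError(f"n_true={n_true} exceeds catalog size {len(catalog)}")
    if jitter_ppm_sd < 0:
        raise ValueError("jitter_ppm_sd must be non-negative")
    adduct_list = [get_adduct(a) for a in adducts]
    rng = np.random.default_rng(seed)

    species_idx = rng.choice(len(catalog), size=n_true, replace=False)
    adduct_idx = rng.integers(0, len(adduct_list), size=n_true)
    queries: list[float] = []
    truth: dict[int, tuple[str, str]] = {}
    for qi, (si, ai) in enumerate(zip(species_idx, adduct_idx)):
        sp = catalog[int(si)]
        a = adduct_list[int(ai)]
        mz = adduct_mz(sp.mass, a)
        jitter = rng.normal(0.0, jitter_ppm_sd) if jitter_ppm_sd > 0 else 0.0
        queries.append(mz * (1.0 + jitter * 1e-6))
        truth[qi] = (sp.name, a.name)

    if n_decoys:
        theo = np.sort(
            [adduct_mz(sp.mass, a) for sp in catalog for a in adduct_list]
        )
        half_width_ppm = 3.0 * jitter_ppm_sd + guard_ppm
        lo, hi = theo[0], theo[-1]
        placed = 0
        attempts = 0
        while placed < n_decoys:
            if attempts >= max_attempts_per_decoy * n_decoys:
                raise ValueError(
                    "could not place guarded decoys: catalog m/z space too "
                    f"dense for a +/-{half_width_ppm:.1f} ppm exclusion window"
                )
            attempts += 1
            x = rng.uniform(lo, hi)
            j = np.searchsorted(theo, x)
            near = [theo[k] for k in (j - 1, j) if 0 <= k < len(theo)]
            if all(abs(x - t) > half_width_ppm * 1e-6 * t for t in near):
                queries.append(float(x))
                placed += 1

    return SyntheticQuerySet(
        queries=tuple(queries),
        truth=truth,
        n_true=n_true,
        n_decoys=n_decoys,
        jitter_ppm_sd=jitter_ppm_sd,
        seed=seed,
    )


def evaluate_annotation(
    query_set: SyntheticQuerySet, matches: list[AnnotationMatch]
) -> dict[str, float]:
    """Score annotation output against the generator's ground truth.

    ``recall`` is the fraction of true queries whose truth (species, adduct)
    appears among their matches; ``false_annotation_count`` is the number of
    matches emitted for decoy queries.
    """
    hits = {
        m.query_index
        for m in matches
        if m.query_index in query_set.truth
        and (m.species.name, m.adduct.name) == query_set.truth[m.query_index]
    }
    recall = len(hits) / query_set.n_true if query_set.n_true else 0.0
    false_count = sum(1 for m in matches if query_set.is_decoy(m.query_index))
    return {"recall": recall, "false_annotation_count": float(false_count)}
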