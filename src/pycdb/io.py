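"""Catalog and match serialization, query ingestion, run configuration.

All files are plain UTF-8 CSV/text with '.' decimals.  Catalog writes are
fully deterministic: the same configuration always produces byte-identical
output, so downloaded catalogs can be diffed across runs and versions.
Monoisotopic masses are printed to 10 decimal places in the catalog;
annotation output prints theoretical m/z to 4 decimals and ppm errors to
1 decimal, the presentation precision customary in accurate-mass work.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .annotate import DEFAULT_TOLERANCE_PPM, AnnotationMatch
from .catalog import EnumerationConfig, SpeciesCatalog

__all__ = [
    "CATALOG_COLUMNS",
    "MATCH_COLUMNS",
    "RunConfig",
    "read_catalog",
    "read_query_masses",
    "write_catalog",
    "write_matches",
]

CATALOG_COLUMNS = [
    "name",
    "aliases",
    "terminal",
    "n",
    "disulfides",
    "metal1",
    "metal2",
    "bridge",
    "formula",
    "monoisotopic_mass",
]

MATCH_COLUMNS = [
    "query_mz",
    "name",
    "formula",
    "adduct",
    "theoretical_mz",
    "ppm_error",
    "terminal",
    "n",
    "disulfides",
    "metals",
    "bridge",
]


def write_catalog(catalog: SpeciesCatalog, path) -> None:
    """Write a catalog as CSV with a fixed schema and deterministic bytes."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CATALOG_COLUMNS)
        for sp in catalog:
            metals = sp.metals + ("",) * (2 - len(sp.metals))
            writer.writerow(
                [
                    sp.name,
                    "|".join(sp.aliases),
                    sp.terminal.label,
                    sp.n,
                    sp.m,
                    metals[0],
                    metals[1],
                    sp.bridge,
                    sp.formula_str,
                    f"{sp.mass:.10f}",
                ]
            )


def read_catalog(path) -> pd.DataFrame:
    """Read a catalog CSV back into a DataFrame (for downstream tooling)."""
    return pd.read_csv(
        path,
        dtype={"metal1": "string", "metal2": "string", "aliases": "string"},
        keep_default_na=False,
    )


def write_matches(matches: Sequence[AnnotationMatch], path) -> None:
    """Write annotation matches as CSV (ppm to 1 decimal, m/z to 4)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MATCH_COLUMNS)
        for m in matches:
            sp = m.species
            writer.writerow(
                [
                    repr(m.query_mz),
                    sp.name,
                    sp.formula_str,
                    m.adduct.name,
                    f"{m.theoretical_mz:.4f}",
                    f"{m.ppm_error:.1f}",
                    sp.terminal.label,
                    sp.n,
                    sp.m,
                    "+".join(sp.metals),
                    sp.bridge,
                ]
            )


def read_query_masses(path) -> list[float]:
    """Read experimental m/z values from a .txt or .csv file.

    ``.txt``: one decimal value per line, blank lines skipped.  ``.csv``: the
    column named ``mz`` (case-insensitive), or the single column if only one
    exists.  Errors report 1-based line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        masses = _read_csv_masses(path)
    else:
        masses = _read_txt_masses(path)
    if not masses:
        raise ValueError(f"{path}: no mass values found")
    return masses


def _parse_positive(token: str, path: Path, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric mass {token!r} at line {lineno}"
        ) from None
    if value <= 0:
        raise ValueError(f"{path}: non-positive mass {value} at line {lineno}")
    return value


def _read_txt_masses(path: Path) -> list[float]:
    masses = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().rstrip(",")
            if token:
                masses.append(_parse_positive(token, path, lineno))
    return masses


def _read_csv_masses(path: Path) -> list[float]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh)]
    rows = [(i, row) for i, row in enumerate(rows, start=1) if any(c.strip() for c in row)]
    if not rows:
        return []
    header = [c.strip().lower() for c in rows[0][1]]
    if "mz" in header:
        col = header.index("mz")
        data = rows[1:]
    elif len(header) == 1:
        # Single column: treat the first row as a header only if non-numeric.
        col = 0
        try:
            float(rows[0][1][0])
            data = rows
        except ValueError:
            data = rows[1:]
    else:
        raise ValueError(f"{path}: no 'mz' column found among {header}")
    return [_parse_positive(row[col].strip(), path, lineno) for lineno, row in data]


@dataclasses.dataclass
class RunConfig:
    """A complete, flat, serializable description of one build/annotate run.

    Every field is reachable both from the command line and from a YAML
    config file; defaults reproduce the published catalog and a 5-ppm
    protonated-adduct search.
    """

    # enumeration
    terminals: tuple[str, ...] = EnumerationConfig().terminals
    n_min: int = 2
    n_max: int = 11
    metals: tuple[str, ...] = EnumerationConfig().metals
    max_metals: int = 2
    include_bridges: bool = True
    max_disulfides: int = 5
    # annotation
    adducts: tuple[str, ...] = ("M+H",)
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM
    nops: bool = False
    filter_metals: tuple[str, ...] | None = None
    filter_terminals: tuple[str, ...] | None = None
    # i/o and reproducibility
    input_path: str | None = None
    output_path: str | None = None
    seed: int = 0
    verbosity: str = "INFO"

    def enumeration_config(self) -> EnumerationConfig:
        return EnumerationConfig(
            terminals=self.terminals,
            n_min=self.n_min,
            n_max=self.n_max,
            metals=self.metals,
            max_metals=self.max_metals,
            include_bridges=self.include_bridges,
            max_disulfides=self.max_disulfides,
        )

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)
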