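"""Celiac-disease epitope catalogue: records, loading and validation.

The catalogue lists HLA-DQ2.5-restricted alpha-gliadin T-cell epitopes and
their single/double-mismatch variants, each with a reported toxicity class:

    T       toxic
    RT      decreased toxicity
    STAR_T  highly likely toxic        (printed as ``*T``)
    NT      not toxic
    STAR_NT highly likely not toxic    (printed as ``*NT``)
    UNK     unknown

The packaged fixture holds the 54 epitopes observed across the eight
synthetic wheat lines; any external catalogue with the same columns (for
example the full 121-epitope literature list) can be loaded instead.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

FAMILIES = ("GLIA_A1", "GLIA_A2", "GLIA_A3", "P31_43", "OTHER")
TOXICITY_CLASSES = ("T", "RT", "STAR_T", "NT", "STAR_NT", "UNK")

# Shorthand class tokens (*T / *NT) accepted on input.
_TOXICITY_ALIASES = {
    "*T": "STAR_T",
    "*NT": "STAR_NT",
}

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# The intact 33-mer: the hallmark D-genome alpha-gliadin fragment carrying
# six overlapping copies of the DQ2.5-Glia-α1a/α1b/α2 epitopes.
THIRTY_THREE_MER = "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF"

# One catalogued peptide, P31-43 (var4), carries an unexplained '*' in its
# recorded sequence.  It is retained for completeness but excluded from
# scanning (its '*' would otherwise collide with the stop-codon convention).
STAR_ANOMALY_PEPTIDE = "LGQ*QPFPPQQPY"


class CatalogueError(ValueError):
    """Raised when a catalogue file violates the record invariants."""


def normalize_name(name: str) -> str:
    """ASCII alias for an epitope name, e.g. ``DQ2.5-glia-a2-var15``.

    Greek letters are transliterated, parentheses dropped and whitespace
    collapsed to single hyphens, giving a shell-friendly identifier.
    """
    out = name.replace("α", "a").replace("γ", "g").replace("ω", "w")
    out = unicodedata.normalize("NFKD", out).encode("ascii", "ignore").decode()
    for ch in "()":
        out = out.replace(ch, " ")
    return "-".join(out.split())


@dataclass(frozen=True)
class EpitopeRecord:
    """A single catalogued epitope peptide."""

    name: str
    family: str
    peptide: str
    toxicity_class: str
    canonical: bool
    novel: bool
    alias: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.alias:
            object.__setattr__(self, "alias", normalize_name(self.name))

    @property
    def scan_excluded(self) -> bool:
        """True for the documented '*'-containing anomaly; never scanned."""
        return "*" in self.peptide


@dataclass(frozen=True)
class ToxicityWeights:
    """Per-class weights for the immunotoxicity load (T/RT/*T = 3/2/1)."""

    weight_T: int = 3
    weight_RT: int = 2
    weight_STAR_T: int = 1

    def __post_init__(self) -> None:
        if min(self.weight_T, self.weight_RT, self.weight_STAR_T) < 0:
            raise ValueError("toxicity weights must be non-negative")

    def weight(self, toxicity_class: str) -> int:
        return {
            "T": self.weight_T,
            "RT": self.weight_RT,
            "STAR_T": self.weight_STAR_T,
        }.get(toxicity_class, 0)


def _validate_row(row: pd.Series, idx: int) -> list[str]:
    errors = []
    peptide = str(row["peptide"])
    if not (9 <= len(peptide) <= 25):
        errors.append(f"row {idx}: peptide length {len(peptide)} outside 9-25")
    if peptide != peptide.upper():
        errors.append(f"row {idx}: peptide must be uppercase")
    bad = set(peptide) - AMINO_ACIDS
    if bad and not (bad == {"*"} and peptide == STAR_ANOMALY_PEPTIDE):
        errors.append(f"row {idx}: non-amino-acid characters {sorted(bad)}")
    if row["family"] not in FAMILIES:
        errors.append(f"row {idx}: unknown family {row['family']!r}")
    return errors


def load_catalogue(path: str | Path, strict: bool = True) -> list[EpitopeRecord]:
    """Load and validate an epitope catalogue TSV.

    Parameters
    ----------
    path:
        Tab-separated file with columns ``name, family, peptide,
        toxicity_class, canonical, novel`` (booleans as 0/1; toxicity as the
        enumeration tokens or the printed ``*T``/``*NT`` forms).
    strict:
        Also enforce family-level invariants: every family other than OTHER
        has at least one canonical record, and GLIA_A1 has exactly two.

    Raises
    ------
    CatalogueError
        listing every offending row, on duplicate names or invalid content.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["name", "family", "peptide", "toxicity_class", "canonical", "novel"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogueError(f"catalogue is missing columns: {missing}")

    errors: list[str] = []
    dupes = df["name"][df["name"].duplicated()].tolist()
    if dupes:
        errors.append(f"duplicate names: {sorted(set(dupes))}")

    records: list[EpitopeRecord] = []
    for idx, row in df.iterrows():
        errors.extend(_validate_row(row, idx))
        tox = _TOXICITY_ALIASES.get(str(row["toxicity_class"]), str(row["toxicity_class"]))
        if tox not in TOXICITY_CLASSES:
            errors.append(f"row {idx}: unknown toxicity class {row['toxicity_class']!r}")
            continue
        records.append(
            EpitopeRecord(
                name=str(row["name"]),
                family=str(row["family"]),
                peptide=str(row["peptide"]),
                toxicity_class=tox,
                canonical=bool(int(row["canonical"])),
                novel=bool(int(row["novel"])),
            )
        )

    if strict and not errors and records:
        by_family: dict[str, list[EpitopeRecord]] = {}
        for rec in records:
            by_family.setdefault(rec.family, []).append(rec)
        for family, recs in by_family.items():
            n_canon = sum(r.canonical for r in recs)
            if family == "OTHER":
                continue
            if n_canon < 1:
                errors.append(f"family {family} has no canonical record")
            if family == "GLIA_A1" and n_canon != 2:
                errors.append(f"family GLIA_A1 must have exactly 2 canonicals, got {n_canon}")

    if errors:
        raise CatalogueError("; ".join(errors))
    return records


def dump_catalogue(records: Sequence[EpitopeRecord], path: str | Path) -> None:
    """Serialize records back to the TSV interchange format."""
    inverse = {"STAR_T": "STAR_T", "STAR_NT": "STAR_NT"}
    df = pd.DataFrame(
        {
            "name": [r.name for r in records],
            "family": [r.family for r in records],
            "peptide": [r.peptide for r in records],
            "toxicity_class": [inverse.get(r.toxicity_class, r.toxicity_class) for r in records],
            "canonical": [int(r.canonical) for r in records],
            "novel": [int(r.novel) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def scannable(records: Iterable[EpitopeRecord]) -> list[EpitopeRecord]:
    """Records eligible for sequence scanning (excludes the '*' anomaly)."""
    return [r for r in records if not r.scan_excluded]


def hamming_to_canonical(record: EpitopeRecord, records: Sequence[EpitopeRecord]) -> int | None:
    """Minimum Hamming distance to any equal-length canonical of its family.

    Returns None when no same-family canonical has the same length (e.g. the
    long P31-43 variants), which callers report as a missing value.
    """
    if record.scan_excluded:
        raise ValueError(f"{record.name} is excluded from scanning")
    candidates = [
        r.peptide
        for r in records
        if r.canonical and r.family == record.family and len(r.peptide) == len(record.peptide)
    ]
    if not candidates:
        return None
    return min(
        sum(a != b for a, b in zip(record.peptide, c)) for c in candidates
    )


def packaged_catalogue_path() -> Path:
    """Path to the packaged 54-epitope catalogue fixture."""
    return Path(resources.files("gliascan").joinpath("data/table2_epitopes.tsv"))


def load_packaged_catalogue() -> list[EpitopeRecord]:
    return load_catalogue(packaged_catalogue_path())


def packaged_presence_path() -> Path:
    """Path to the packaged per-line presence/absence fixture."""
    return Path(resources.files("gliascan").joinpath("data/table2_presence.tsv"))


def load_packaged_presence() -> pd.DataFrame:
    """Presence/absence matrix (rows = epitopes, columns = lines) as 0/1."""
    return pd.read_csv(packaged_presence_path(), sep="\t", index_col="name")
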