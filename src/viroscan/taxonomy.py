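"""Hierarchical viral taxonomy: genome accession → species → genus → family.

The reference databases are genome collections; the lineage is made explicit
as a required 4-column sidecar TSV (accession, species, genus, family) so that
custom databases are first-class. Counting is at species resolution: strain
records collapse to their species string.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd

__all__ = ["Lineage", "TaxonomyTable", "TaxonomyError", "load_taxonomy", "rollup"]

LEVELS = ("species", "genus", "family")


class TaxonomyError(ValueError):
    pass


class Lineage(NamedTuple):
    species: str
    genus: str
    family: str


@dataclass
class TaxonomyTable:
    """Validated accession → lineage mapping.

    Invariants: one lineage per accession; no empty level names; each species
    maps to exactly one (genus, family) pair.
    """

    rows: dict[str, Lineage]

    def __post_init__(self) -> None:
        species_parent: dict[str, tuple[str, str]] = {}
        for acc, lin in self.rows.items():
            if not (lin.species and lin.genus and lin.family):
                raise TaxonomyError(f"accession {acc!r}: empty lineage field")
            parent = (lin.genus, lin.family)
            prev = species_parent.setdefault(lin.species, parent)
            if prev != parent:
                raise TaxonomyError(
                    f"species {lin.species!r} mapped to two lineages: "
                    f"{prev} and {parent}"
                )
        self._species_parent = species_parent

    def __contains__(self, accession: str) -> bool:
        return accession in self.rows

    def __len__(self) -> int:
        return len(self.rows)

    def lineage(self, accession: str) -> Lineage:
        try:
            return self.rows[accession]
        except KeyError:
            raise TaxonomyError(f"accession {accession!r} not in taxonomy") from None

    def species_of(self, accession: str) -> str:
        return self.lineage(accession).species

    def parent_of_species(self, species: str) -> tuple[str, str]:
        """(genus, family) of a species."""
        try:
            return self._species_parent[species]
        except KeyError:
            raise TaxonomyError(f"species {species!r} not in taxonomy") from None


def load_taxonomy(path: str | Path) -> TaxonomyTable:
    """Load the 4-column taxonomy sidecar TSV (header line required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["accession", "species", "genus", "family"]
    if list(df.columns[:4]) != expected:
        raise TaxonomyError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    dup = df["accession"][df["accession"].duplicated()]
    if not dup.empty:
        raise TaxonomyError(f"{path}: duplicate accession {dup.iloc[0]!r}")
    rows = {
        r.accession: Lineage(r.species, r.genus, r.family)
        for r in df.itertuples(index=False)
    }
    return TaxonomyTable(rows)


def save_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("accession\tspecies\tgenus\tfamily\n")
        for acc, lin in table.rows.items():
            fh.write(f"{acc}\t{lin.species}\t{lin.genus}\t{lin.family}\n")


def rollup(
    species_counts: Mapping[str, int], table: TaxonomyTable
) -> dict[str, dict[str, int]]:
    """Aggregate species-level counts to genus and family.

    Total counts are conserved at every level; a species key absent from the
    taxonomy is fatal.
    """
    genus: dict[str, int] = {}
    family: dict[str, int] = {}
    for species, count in species_counts.items():
        if count < 0:
            raise ValueError(f"negative count for species {species!r}")
        g, f = table.parent_of_species(species)
        genus[g] = genus.get(g, 0) + count
        family[f] = family.get(f, 0) + count
    return {"genus": genus, "family": family}
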