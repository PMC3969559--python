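"""Taxonomy table: sequence id -> species, taxonomic group, domain, supergroup.

Every tree in the pipeline is read through a :class:`TaxonomyMap`. Groups are
phyla, except for Proteobacteria and Firmicutes which are sampled class-wise
(Alphaproteobacteria, Bacilli, ...). Eukaryotic sequences additionally carry
one of four supergroup labels (Unikonts, Plantae, Chromalveolates,
Kinetoplastids) or OtherEukaryote; prokaryotes carry the supergroup
placeholder ``NA``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

DOMAINS = ("Bacteria", "Archaea", "Eukarya")
PROK_DOMAINS = ("Archaea", "Bacteria")
SUPERGROUPS = ("Unikonts", "Plantae", "Chromalveolates", "Kinetoplastids",
               "OtherEukaryote")
NA = "NA"

TAXONOMY_COLUMNS = ("sequence_id", "species_id", "group", "domain", "supergroup")


class TaxonomyError(ValueError):
    """Invalid taxonomy table or a leaf that violates its invariants."""


@dataclass(frozen=True)
class TaxonRecord:
    sequence_id: str
    species_id: str
    group: str
    domain: str
    supergroup: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise TaxonomyError(
                f"unknown domain {self.domain!r} for sequence {self.sequence_id!r}"
            )
        if self.domain == "Eukarya":
            if self.supergroup not in SUPERGROUPS:
                raise TaxonomyError(
                    f"eukaryotic sequence {self.sequence_id!r} needs a supergroup, "
                    f"got {self.supergroup!r}"
                )
        elif self.supergroup != NA:
            raise TaxonomyError(
                f"prokaryotic sequence {self.sequence_id!r} must have supergroup NA, "
                f"got {self.supergroup!r}"
            )

    @property
    def is_eukaryote(self) -> bool:
        return self.domain == "Eukarya"

    @property
    def is_prokaryote(self) -> bool:
        return self.domain != "Eukarya"


class TaxonomyMap:
    """Immutable mapping from sequence id to its taxonomic record.

    Invariants enforced at construction: sequence ids are unique; a species
    maps to exactly one (group, domain); supergroup is set iff the domain is
    Eukarya.
    """

    def __init__(self, records: Iterable[TaxonRecord]):
        self._records: dict[str, TaxonRecord] = {}
        species_identity: dict[str, tuple[str, str]] = {}
        for rec in records:
            if rec.sequence_id in self._records:
                raise TaxonomyError(f"duplicate sequence_id {rec.sequence_id!r}")
            seen = species_identity.get(rec.species_id)
            identity = (rec.group, rec.domain)
            if seen is not None and seen != identity:
                raise TaxonomyError(
                    f"species {rec.species_id!r} maps to both {seen} and {identity}"
                )
            species_identity[rec.species_id] = identity
            self._records[rec.sequence_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self._records

    def __getitem__(self, sequence_id: str) -> TaxonRecord:
        try:
            return self._records[sequence_id]
        except KeyError:
            raise TaxonomyError(
                f"sequence {sequence_id!r} is absent from the taxonomy map"
            ) from None

    def get(self, sequence_id: str) -> TaxonRecord | None:
        return self._records.get(sequence_id)

    @property
    def records(self) -> tuple[TaxonRecord, ...]:
        return tuple(self._records.values())

    # --- convenience views -------------------------------------------------

    def species(self, sequence_id: str) -> str:
        return self[sequence_id].species_id

    def group(self, sequence_id: str) -> str:
        return self[sequence_id].group

    def domain(self, sequence_id: str) -> str:
        return self[sequence_id].domain

    def supergroup(self, sequence_id: str) -> str:
        return self[sequence_id].supergroup

    def is_eukaryote(self, sequence_id: str) -> bool:
        return self[sequence_id].is_eukaryote

    def eukaryote_leaves(self, labels: Iterable[str]) -> frozenset[str]:
        return frozenset(x for x in labels if self[x].is_eukaryote)

    def prokaryote_leaves(self, labels: Iterable[str]) -> frozenset[str]:
        return frozenset(x for x in labels if self[x].is_prokaryote)

    def species_of(self, labels: Iterable[str]) -> frozenset[str]:
        """Distinct species ids represented by the given sequence labels."""
        return frozenset(self[x].species_id for x in labels)

    def species_by_domain(self, labels: Iterable[str]) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {d: set() for d in DOMAINS}
        for x in labels:
            rec = self[x]
            out[rec.domain].add(rec.species_id)
        return out

    def domain_species_totals(self) -> dict[str, int]:
        """Number of distinct species per domain over the whole map."""
        per_domain: dict[str, set[str]] = {d: set() for d in DOMAINS}
        for rec in self._records.values():
            per_domain[rec.domain].add(rec.species_id)
        return {d: len(s) for d, s in per_domain.items()}

    def missing(self, labels: Iterable[str]) -> list[str]:
        return sorted(x for x in labels if x not in self._records)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a tab-separated taxonomy table with a header row.

    Required columns: sequence_id, species_id, group, domain, supergroup.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise TaxonomyError(f"{path}: empty taxonomy file")
        missing = [c for c in TAXONOMY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TaxonomyError(f"{path}: missing columns {missing}")
        records = [
            TaxonRecord(
                sequence_id=row["sequence_id"].strip(),
                species_id=row["species_id"].strip(),
                group=row["group"].strip(),
                domain=row["domain"].strip(),
                supergroup=row["supergroup"].strip(),
            )
            for row in reader
        ]
    return TaxonomyMap(records)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TAXONOMY_COLUMNS)
        for rec in tax.records:
            writer.writerow([rec.sequence_id, rec.species_id, rec.group,
                             rec.domain, rec.supergroup])


def taxonomy_from_mapping(rows: Iterable[Mapping[str, str]]) -> TaxonomyMap:
    """Build a TaxonomyMap from dict-like rows (mostly for tests/simulation)."""
    return TaxonomyMap(TaxonRecord(**{k: row[k] for k in TAXONOMY_COLUMNS})
                       for row in rows)
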