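"""Strain manifests for a ribosomal-variant-strain (RVS) screening library.

A manifest records, for every strain in the library, which ribosomal-protein
gene is heterozygously deleted, whether that gene is single-copy or one of a
duplicated paralog pair, and whether the strain is viable under the screen's
culture conditions.  The wild-type vehicle is carried alongside: the number
of usable screening vehicles is ``1 (wild type) + number of viable strains``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._rp_genes import (
    DUPLICATED_GENE_BASES,
    NONVIABLE_GENES,
    SINGLE_COPY_GENES,
    protein_label,
)

__all__ = [
    "StrainRecord",
    "StrainManifest",
    "build_strain_manifest",
    "read_manifest",
    "write_manifest",
    "NONVIABLE_GENES",
]


@dataclass(frozen=True)
class StrainRecord:
    """One library strain: a heterozygous deletion of one RP gene."""

    gene_id: str
    protein_id: str
    copy_class: str  # "single" or "duplicated"
    paralog_partner: str | None
    viable: bool

    def __post_init__(self) -> None:
        if self.copy_class not in ("single", "duplicated"):
            raise ValueError(f"bad copy_class {self.copy_class!r} for {self.gene_id}")
        if self.copy_class == "duplicated" and not self.paralog_partner:
            raise ValueError(f"duplicated gene {self.gene_id} lacks a paralog partner")
        if self.copy_class == "single" and self.paralog_partner:
            raise ValueError(f"single-copy gene {self.gene_id} must not have a partner")


@dataclass
class StrainManifest:
    """Ordered collection of strain records plus the wild-type vehicle id."""

    strains: list[StrainRecord] = field(default_factory=list)
    wildtype_id: str = "WT"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.gene_id for s in self.strains]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in manifest: {dupes}")
        if self.wildtype_id in ids:
            raise ValueError(f"wildtype id {self.wildtype_id!r} collides with a strain")
        by_id = {s.gene_id: s for s in self.strains}
        for s in self.strains:
            if s.copy_class == "duplicated":
                partner = by_id.get(s.paralog_partner)
                if partner is None:
                    raise ValueError(
                        f"{s.gene_id}: partner {s.paralog_partner!r} not in manifest"
                    )
                if partner.paralog_partner != s.gene_id:
                    raise ValueError(
                        f"paralog pointers disagree: {s.gene_id} <-> {partner.gene_id}"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return [s.gene_id for s in self.strains]

    @property
    def viable_strains(self) -> list[StrainRecord]:
        return [s for s in self.strains if s.viable]

    @property
    def n_usable_vehicles(self) -> int:
        """Wild type plus every viable strain."""
        return 1 + len(self.viable_strains)

    def record(self, gene_id: str) -> StrainRecord:
        for s in self.strains:
            if s.gene_id == gene_id:
                return s
        raise KeyError(gene_id)


def _synthetic_names(n_single: int, n_pairs: int) -> tuple[list[str], list[tuple[str, str]]]:
    singles = [f"G{i + 1}" for i in range(n_single)]
    pairs = [
        (f"G{n_single + i + 1}A", f"G{n_single + i + 1}B") for i in range(n_pairs)
    ]
    return singles, pairs


def build_strain_manifest(
    n_single: int,
    n_pairs: int,
    nonviable_ids: Iterable[str] = (),
    wildtype_id: str = "WT",
) -> StrainManifest:
    """Build a manifest of ``n_single + 2 * n_pairs`` strains.

    With ``n_single=19, n_pairs=59`` the packaged yeast RP gene list is used
    (137 genes); any other shape gets synthetic names ``G1..`` with ``A``/``B``
    suffixes for pairs.  Strains named in ``nonviable_ids`` are flagged
    non-viable; naming an unknown gene is an error.
    """
    if n_single < 0 or n_pairs < 0:
        raise ValueError("n_single and n_pairs must be non-negative")
    if (n_single, n_pairs) == (len(SINGLE_COPY_GENES), len(DUPLICATED_GENE_BASES)):
        singles = list(SINGLE_COPY_GENES)
        pairs = [(b + "A", b + "B") for b in DUPLICATED_GENE_BASES]
        label = protein_label
    else:
        singles, pairs = _synthetic_names(n_single, n_pairs)

        def label(gene_id: str) -> str:
            return "p" + gene_id

    nonviable = set(nonviable_ids)
    known = set(singles) | {g for pair in pairs for g in pair}
    unknown = sorted(nonviable - known)
    if unknown:
        raise ValueError(f"unknown non-viable gene id(s): {', '.join(unknown)}")

    records = [
        StrainRecord(g, label(g), "single", None, g not in nonviable) for g in singles
    ]
    for a, b in pairs:
        records.append(StrainRecord(a, label(a), "duplicated", b, a not in nonviable))
        records.append(StrainRecord(b, label(b), "duplicated", a, b not in nonviable))
    return StrainManifest(strains=records, wildtype_id=wildtype_id)


_MANIFEST_COLUMNS = ["gene_id", "protein_id", "copy_class", "paralog_partner", "viable"]


def write_manifest(manifest: StrainManifest, path: str | Path) -> Path:
    """Write a manifest as CSV; the wild-type id is kept in a header comment."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# wildtype_id={manifest.wildtype_id}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_MANIFEST_COLUMNS)
        for s in manifest.strains:
            writer.writerow(
                [
                    s.gene_id,
                    s.protein_id,
                    s.copy_class,
                    s.paralog_partner or "",
                    "true" if s.viable else "false",
                ]
            )
    return path


def read_manifest(path: str | Path) -> StrainManifest:
    path = Path(path)
    wildtype_id = "WT"
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            if "wildtype_id=" in first:
                wildtype_id = first.split("wildtype_id=", 1)[1].strip()
            header_line = fh.readline().strip()
        else:
            header_line = first
        header = header_line.split(",")
        if header != _MANIFEST_COLUMNS:
            missing = sorted(set(_MANIFEST_COLUMNS) - set(header))
            raise ValueError(f"manifest header missing column(s): {', '.join(missing)}")
        records = []
        for row in csv.DictReader(fh, fieldnames=header):
            records.append(
                StrainRecord(
                    gene_id=row["gene_id"],
                    protein_id=row["protein_id"],
                    copy_class=row["copy_class"],
                    paralog_partner=row["paralog_partner"] or None,
                    viable=row["viable"].strip().lower() in ("true", "1", "yes"),
                )
            )
    return StrainManifest(strains=records, wildtype_id=wildtype_id)
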