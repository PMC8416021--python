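"""Guide-RNA library loading, validation and spacer lookup.

A pooled CRISPR library is a table of guides, each with a unique identifier,
a target gene symbol and a spacer (the 19-20 nt variable region that ends up
in sequencing reads).  Counting reads against the library reduces to exact
lookup of an extracted spacer in this table, so the index built here maps
spacer sequence -> guide id(s) and records spacers shared by several guides
explicitly rather than dropping them.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GuideRecord",
    "LibraryIndex",
    "LibraryError",
    "load_library",
    "write_library",
    "build_index",
    "lookup_spacer",
    "library_qc",
]

_DNA = frozenset("ACGT")

DEFAULT_COLUMNS = {"guide_id": "guide_id", "gene": "gene", "spacer": "spacer"}


class LibraryError(ValueError):
    """Raised for malformed or inconsistent library files."""


@dataclass(frozen=True)
class GuideRecord:
    """One library guide: identifier, target gene, spacer sequence."""

    guide_id: str
    gene: str
    spacer: str

    def __post_init__(self) -> None:
        if not self.guide_id:
            raise LibraryError("guide_id must be non-empty")
        if not self.gene:
            raise LibraryError(f"guide {self.guide_id!r}: gene must be non-empty")
        spacer = self.spacer.upper()
        if not spacer:
            raise LibraryError(f"guide {self.guide_id!r}: empty spacer")
        bad = set(spacer) - _DNA
        if bad:
            raise LibraryError(
                f"guide {self.guide_id!r}: spacer contains non-ACGT "
                f"character(s) {sorted(bad)} (RNA 'U' is rejected; the library "
                "is DNA)"
            )
        object.__setattr__(self, "spacer", spacer)


@dataclass
class LibraryIndex:
    """Validated guide library with a spacer -> guide_id lookup table.

    ``spacer_map`` values are lexicographically sorted guide-id lists so that
    ambiguous lookups are deterministic.  ``ambiguous_spacers`` holds exactly
    the spacers carried by two or more guides.
    """

    records: list[GuideRecord]
    spacer_map: dict[str, list[str]] = field(repr=False)
    ambiguous_spacers: set[str] = field(repr=False)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> dict[str, str]:
        """guide_id -> gene mapping."""
        return {r.guide_id: r.gene for r in self.records}

    def guides_per_gene(self) -> dict[str, int]:
        counts: Counter[str] = Counter(r.gene for r in self.records)
        return dict(counts)


def build_index(records: Iterable[GuideRecord]) -> LibraryIndex:
    """Index records by spacer, enforcing guide_id uniqueness."""
    records = list(records)
    seen: set[str] = set()
    for r in records:
        if r.guide_id in seen:
            raise LibraryError(f"duplicate guide_id {r.guide_id!r}")
        seen.add(r.guide_id)
    spacer_map: dict[str, list[str]] = {}
    for r in records:
        spacer_map.setdefault(r.spacer, []).append(r.guide_id)
    for ids in spacer_map.values():
        ids.sort()
    ambiguous = {s for s, ids in spacer_map.items() if len(ids) >= 2}
    return LibraryIndex(records=records, spacer_map=spacer_map, ambiguous_spacers=ambiguous)


def load_library(
    path: str | Path,
    column_spec: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> LibraryIndex:
    """Load a delimited-text guide library and build its spacer index.

    Parameters
    ----------
    path
        Library table with a header row.  The default dialect is
        tab-separated with columns ``guide_id``, ``gene``, ``spacer``.
    column_spec
        Optional remapping ``{"guide_id": <col>, "gene": <col>,
        "spacer": <col>}`` for other published library layouts.
    sep
        Field separator.

    Raises
    ------
    LibraryError
        Empty file, missing columns, duplicate guide ids or non-ACGT
        spacers; messages name the offending line.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_spec:
        cols.update(column_spec)

    lines = [
        (i, line.rstrip("\n"))
        for i, line in enumerate(path.read_text().splitlines(), start=1)
        if line.strip()
    ]
    if not lines:
        raise LibraryError(f"{path}: empty library file")
    header = lines[0][1].split(sep)
    try:
        idx = {k: header.index(cols[k]) for k in ("guide_id", "gene", "spacer")}
    except ValueError as exc:
        raise LibraryError(
            f"{path}: header {header!r} lacks required column ({exc})"
        ) from None

    records: list[GuideRecord] = []
    seen: set[str] = set()
    for lineno, line in lines[1:]:
        fields = line.split(sep)
        if len(fields) < len(header):
            raise LibraryError(f"{path}:{lineno}: expected {len(header)} fields")
        gid = fields[idx["guide_id"]].strip()
        try:
            rec = GuideRecord(
                guide_id=gid,
                gene=fields[idx["gene"]].strip(),
                spacer=fields[idx["spacer"]].strip(),
            )
        except LibraryError as exc:
            raise LibraryError(f"{path}:{lineno}: {exc}") from None
        if rec.guide_id in seen:
            raise LibraryError(f"{path}:{lineno}: duplicate guide_id {rec.guide_id!r}")
        seen.add(rec.guide_id)
        records.append(rec)
    if not records:
        raise LibraryError(f"{path}: no guide records (header only)")
    return build_index(records)


def write_library(index: LibraryIndex, path: str | Path) -> None:
    """Write a validated library back to the default TSV dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("guide_id\tgene\tspacer\n")
        for r in index.records:
            fh.write(f"{r.guide_id}\t{r.gene}\t{r.spacer}\n")


def lookup_spacer(index: LibraryIndex, spacer: str) -> list[str]:
    """All guide ids whose library spacer equals ``spacer`` exactly.

    Matching is strand-literal and case-sensitive on the uppercase-normalized
    library; an unmatched query returns an empty list (not an error).
    Ambiguous spacers return every carrier, lexicographically ordered.
    """
    return list(index.spacer_map.get(spacer, ()))


def library_qc(index: LibraryIndex) -> dict:
    """QC summary: record count, spacer-length histogram, ambiguity count."""
    lengths = Counter(len(r.spacer) for r in index.records)
    return {
        "n_records": len(index.records),
        "n_genes": len({r.gene for r in index.records}),
        "spacer_length_histogram": {str(k): v for k, v in sorted(lengths.items())},
        "n_ambiguous_spacers": len(index.ambiguous_spacers),
        "n_distinct_spacers": len(index.spacer_map),
    }


def write_library_qc(index: LibraryIndex, path: str | Path) -> None:
    Path(path).write_text(json.dumps(library_qc(index), indent=2, sort_keys=True) + "\n")
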