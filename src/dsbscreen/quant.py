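"""Spacer extraction from single-end screen reads and per-guide counting.

Screen amplicons have a fixed layout: a constant vector segment (anchor)
immediately upstream of the variable spacer, and the invariant scaffold
immediately downstream.  Extraction locates the upstream anchor with a
bounded-Hamming scan, takes the following bases as the spacer (trimmed at
the downstream anchor when it is visible in the read), and assigns the
spacer to a guide by exact lookup in the library index.  Every read lands in
exactly one QC tally, so totals are conserved and counts are auditable.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import LibraryIndex, lookup_spacer

__all__ = [
    "AnchorConfig",
    "ExtractionReason",
    "ExtractionResult",
    "CountTable",
    "extract_spacer",
    "count_reads",
    "read_sample_sheet",
]

# Canonical pKLV context flanking the spacer: end of the U6 promoter and the
# start of the gRNA scaffold.  These are defaults, not measured values; real
# runs should set them to match the amplicon design.
DEFAULT_ANCHOR5 = "TGGAAAGGACGAAACACCG"
DEFAULT_ANCHOR3 = "GTTTAAGAGCTAAGCTGGAA"

# Minimum bases of the downstream anchor that must be visible at the end of
# a truncated read before a prefix occurrence counts as found.
_MIN_ANCHOR3_OVERLAP = 3


class ExtractionReason(str, Enum):
    OK = "ok"
    NO_ANCHOR = "no_anchor"
    BAD_LENGTH = "bad_length"


@dataclass(frozen=True)
class ExtractionResult:
    spacer: str | None
    reason: ExtractionReason

    def __post_init__(self) -> None:
        if (self.spacer is not None) != (self.reason is ExtractionReason.OK):
            raise ValueError("spacer must be present iff reason is 'ok'")


@dataclass(frozen=True)
class AnchorConfig:
    """Where the spacer sits in a read.

    ``anchor5`` is required; ``anchor3`` may be empty (short reads that end
    inside the spacer).  ``max_anchor_mismatches`` bounds the Hamming
    distance of an anchor occurrence; indels are not modelled because the
    amplicon layout is fixed.
    """

    anchor5: str = DEFAULT_ANCHOR5
    anchor3: str = DEFAULT_ANCHOR3
    max_anchor_mismatches: int = 1
    spacer_length_range: tuple[int, int] = (19, 20)

    def __post_init__(self) -> None:
        if not self.anchor5:
            raise ValueError("anchor5 must be non-empty")
        lo, hi = self.spacer_length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid spacer_length_range {self.spacer_length_range}")
        if not 0 <= self.max_anchor_mismatches < len(self.anchor5):
            raise ValueError("max_anchor_mismatches must be in [0, len(anchor5))")


def _hamming_within(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, early-exiting above limit."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _best_anchor5(read: str, cfg: AnchorConfig) -> int | None:
    """Start offset of the best anchor5 occurrence (leftmost on ties)."""
    anchor = cfg.anchor5
    # Exact hits are both minimal and, via str.find, leftmost.
    pos = read.find(anchor)
    if pos >= 0:
        return pos
    if cfg.max_anchor_mismatches == 0:
        return None
    best_pos, best_mm = None, cfg.max_anchor_mismatches + 1
    n = len(read) - len(anchor)
    for i in range(n + 1):
        mm = _hamming_within(read[i : i + len(anchor)], anchor, best_mm - 1)
        if mm < best_mm:
            best_pos, best_mm = i, mm
            if mm == 0:
                break
    return best_pos


def _anchor3_at(read: str, pos: int, cfg: AnchorConfig) -> bool:
    """Does anchor3 occur at ``pos``, allowing truncation at the read end?"""
    a3 = cfg.anchor3
    avail = len(read) - pos
    if avail <= 0:
        return False
    k = min(len(a3), avail)
    if k < min(len(a3), _MIN_ANCHOR3_OVERLAP):
        return False
    return _hamming_within(read[pos : pos + k], a3[:k], cfg.max_anchor_mismatches) \
        <= cfg.max_anchor_mismatches


def extract_spacer(read_sequence: str, cfg: AnchorConfig) -> ExtractionResult:
    """Pull the spacer out of one read.

    The best anchor5 occurrence (fewest mismatches, leftmost on ties) fixes
    the spacer start.  If anchor3 occurs at a distance within
    ``spacer_length_range`` of the anchor end, the spacer is trimmed there
    (shortest placement wins); otherwise the next max-length bases are
    taken.  A segment outside the length range gives ``bad_length``.  ``N``
    bases are kept in the returned spacer — exact library lookup rejects
    them downstream.
    """
    read = read_sequence.upper()
    lo, hi = cfg.spacer_length_range
    if len(read) < len(cfg.anchor5) + lo:
        return ExtractionResult(None, ExtractionReason.NO_ANCHOR)
    pos = _best_anchor5(read, cfg)
    if pos is None:
        return ExtractionResult(None, ExtractionReason.NO_ANCHOR)
    start = pos + len(cfg.anchor5)
    if cfg.anchor3:
        for length in range(lo, hi + 1):
            if _anchor3_at(read, start + length, cfg):
                return ExtractionResult(read[start : start + length], ExtractionReason.OK)
    spacer = read[start : start + hi]
    if not lo <= len(spacer) <= hi:
        return ExtractionResult(None, ExtractionReason.BAD_LENGTH)
    return ExtractionResult(spacer, ExtractionReason.OK)


_QC_KEYS = (
    "total_reads",
    "extracted",
    "no_anchor",
    "bad_length",
    "matched",
    "unmatched_spacer",
    "ambiguous_assigned",
    "ambiguous_discarded",
)


@dataclass
class CountTable:
    """Guides x samples raw counts with per-sample QC tallies.

    ``counts`` is indexed by guide_id in library order; columns are sample
    names.  Counts are integers under the ``discard`` ambiguity policy and
    may be fractional under ``fractional`` (1/k per carrier guide).
    """

    counts: pd.DataFrame
    genes: pd.Series = field(repr=False)
    qc: dict[str, dict[str, float]] = field(repr=False)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene", self.genes)
        out.to_csv(path, sep="\t", index_label="guide_id", float_format="%.10g")

    def write_qc(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.qc, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="guide_id")
        genes = df.pop("gene")
        return cls(counts=df, genes=genes, qc={})


def _open_maybe_gzip(path: Path) -> Iterator[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")  # type: ignore[return-value]
    return path.open()


def _iter_fastq(path: Path) -> Iterator[tuple[int, str]]:
    """Yield (record_number, sequence); re-raise parse errors with position."""
    recno = 0
    with _open_maybe_gzip(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                _title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"{path}: ill-formed FASTQ record {recno + 1}: {exc}") from None
            recno += 1
            yield recno, seq


def _rescue_lookup(index: LibraryIndex, spacer: str, max_mm: int) -> list[str]:
    """Mismatch-tolerant lookup: unique library spacer within max_mm, else []."""
    hits: list[str] = []
    for lib_spacer, ids in index.spacer_map.items():
        if len(lib_spacer) != len(spacer):
            continue
        if _hamming_within(spacer, lib_spacer, max_mm) <= max_mm:
            hits.append(lib_spacer)
            if len(hits) > 1:
                return []  # multiple candidate spacers: cannot disambiguate
    return list(index.spacer_map[hits[0]]) if hits else []


def count_reads(
    fastq_paths: Mapping[str, str | Path],
    index: LibraryIndex,
    cfg: AnchorConfig | None = None,
    ambiguous_policy: str = "discard",
    spacer_mismatch: int = 0,
) -> CountTable:
    """Count reads per guide for each sample.

    Parameters
    ----------
    fastq_paths
        Mapping sample name -> FASTQ path (plain or gzip).
    ambiguous_policy
        ``discard`` (default) drops reads whose spacer is carried by >=2
        guides; ``fractional`` credits 1/k to each of the k carriers.
    spacer_mismatch
        0 (default) requires exact spacer identity; 1 enables a
        single-mismatch rescue for spacers matching a unique library spacer.

    Guides never observed get count 0.  Every read contributes to exactly
    one of: no_anchor, bad_length, matched, unmatched_spacer,
    ambiguous_discarded (matched includes fractional ambiguous assignment).
    """
    if cfg is None:
        cfg = AnchorConfig()
    if ambiguous_policy not in ("discard", "fractional"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    guide_ids = [r.guide_id for r in index.records]
    genes = pd.Series({r.guide_id: r.gene for r in index.records}, name="gene").loc[guide_ids]

    spacer_map = index.spacer_map
    data: dict[str, list[float]] = {}
    qc_all: dict[str, dict[str, float]] = {}
    pos_of = {g: i for i, g in enumerate(guide_ids)}

    for sample, fq in fastq_paths.items():
        if sample in qc_all:
            raise ValueError(f"sample name collision: {sample!r}")
        counts = [0.0] * len(guide_ids)
        qc = dict.fromkeys(_QC_KEYS, 0.0)
        for _recno, seq in _iter_fastq(Path(fq)):
            qc["total_reads"] += 1
            res = extract_spacer(seq, cfg)
            if res.reason is ExtractionReason.NO_ANCHOR:
                qc["no_anchor"] += 1
                continue
            if res.reason is ExtractionReason.BAD_LENGTH:
                qc["bad_length"] += 1
                continue
            qc["extracted"] += 1
            ids = spacer_map.get(res.spacer, ())
            if not ids and spacer_mismatch > 0:
                ids = _rescue_lookup(index, res.spacer, spacer_mismatch)
            if not ids:
                qc["unmatched_spacer"] += 1
            elif len(ids) == 1:
                qc["matched"] += 1
                counts[pos_of[ids[0]]] += 1
            elif ambiguous_policy == "discard":
                qc["ambiguous_discarded"] += 1
            else:
                qc["matched"] += 1
                qc["ambiguous_assigned"] += 1
                share = 1.0 / len(ids)
                for g in ids:
                    counts[pos_of[g]] += share
        data[sample] = counts
        qc_all[sample] = qc

    counts_df = pd.DataFrame(data, index=pd.Index(guide_ids, name="guide_id"))
    return CountTable(counts=counts_df, genes=genes, qc=qc_all)


def read_sample_sheet(path: str | Path) -> tuple[dict[str, Path], dict[str, str]]:
    """Parse a ``sample  fastq_path  role`` TSV; returns (paths, roles)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "fastq_path", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: sample name collision: {dups}")
    bad_roles = set(df["role"]) - {"high", "low", "unsorted"}
    if bad_roles:
        raise ValueError(f"{path}: unknown role(s) {sorted(bad_roles)}")
    paths = {row["sample"]: Path(row["fastq_path"]) for _, row in df.iterrows()}
    roles = dict(zip(df["sample"], df["role"]))
    return paths, roles
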