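"""Resection profiling at programmed cut sites from strand-aware end records.

End sequencing captures the exact genomic position of every double-strand
break end.  Around a blunt cut, unresected ends pile up at the cut itself,
while nucleolytic resection moves the sequenced end away from the cut —
rightwards on the top (+) strand, leftwards on the bottom (−) strand.  This
module aggregates already-aligned end records (BED) around known cut sites
(e.g. AsiSI positions), bins them into distance profiles, and summarizes
per-site resection extent as a high quantile of end-to-cut distances.

Coordinates are 0-based half-open throughout (BED convention); a site's
window is [cut - W, cut + W).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CutSite",
    "EndAlignment",
    "AssignedEnds",
    "ResectionProfile",
    "read_sites_bed",
    "read_ends_bed",
    "write_sites_bed",
    "write_ends_bed",
    "assign_ends",
    "resection_extent",
    "build_profiles",
    "heatmap_matrix",
    "compare_genotypes",
]

DEFAULT_WINDOW = 5000
DEFAULT_BIN_SIZE = 25
DEFAULT_QUANTILE = 0.95
DEFAULT_MIN_SUPPORT = 5

SIDES = ("left", "right")


@dataclass(frozen=True)
class CutSite:
    chrom: str
    position: int  # 0-based coordinate of the break point
    site_id: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"site {self.site_id!r}: negative position")


@dataclass(frozen=True)
class EndAlignment:
    chrom: str
    end_position: int  # 0-based coordinate of the sequenced DNA end
    strand: str

    def __post_init__(self) -> None:
        if self.end_position < 0:
            raise ValueError("negative end_position")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class AssignedEnds:
    """Per-site signed distances and sides, plus the unassigned tally.

    ``by_site`` maps site_id -> list of (distance, side) where distance =
    end_position − cut position (in [−W, W)) and side is 'right' for
    +-strand ends, 'left' for −-strand ends.
    """

    by_site: dict[str, list[tuple[int, str]]]
    unassigned: int
    window: int

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_site.values())


def read_sites_bed(path: str | Path) -> list[CutSite]:
    """Cut sites from BED (chrom, start, end, site_id); cut = start."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "site_id"], usecols=range(4),
        dtype={"chrom": str, "site_id": str},
    )
    sites = [CutSite(r.chrom, int(r.start), r.site_id) for r in df.itertuples()]
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate site_id(s): {dup}")
    return sites


def read_ends_bed(path: str | Path) -> list[EndAlignment]:
    """End records from BED6; the end coordinate is column 2 (start)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"], usecols=range(6),
        dtype={"chrom": str, "strand": str},
    )
    return [EndAlignment(r.chrom, int(r.start), r.strand) for r in df.itertuples()]


def write_sites_bed(sites: Iterable[CutSite], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.site_id}\n")


def write_ends_bed(ends: Iterable[EndAlignment], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for i, e in enumerate(ends):
            fh.write(
                f"{e.chrom}\t{e.end_position}\t{e.end_position + 1}\tend{i}\t0\t{e.strand}\n"
            )


def _check_site_spacing(sites: Sequence[CutSite], window: int) -> None:
    by_chrom: dict[str, list[CutSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom_sites in by_chrom.values():
        chrom_sites.sort(key=lambda s: s.position)
        for a, b in zip(chrom_sites, chrom_sites[1:]):
            if b.position - a.position < 2 * window:
                raise ValueError(
                    f"site windows overlap: {a.site_id!r} at {a.chrom}:{a.position} "
                    f"and {b.site_id!r} at {b.chrom}:{b.position} are closer than "
                    f"2 x window ({2 * window} bp)"
                )


def assign_ends(
    ends: Sequence[EndAlignment],
    sites: Sequence[CutSite],
    window: int = DEFAULT_WINDOW,
) -> AssignedEnds:
    """Assign each end to the unique site whose window [cut−W, cut+W) holds it.

    Site windows must not overlap (sites closer than 2·window on one
    chromosome are an error).  Ends outside every window are dropped into
    the ``unassigned`` tally, so assigned + unassigned = input ends.
    """
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate site_id in sites")
    _check_site_spacing(sites, window)

    positions: dict[str, np.ndarray] = {}
    site_ids: dict[str, list[str]] = {}
    by_chrom: dict[str, list[CutSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, chrom_sites in by_chrom.items():
        chrom_sites.sort(key=lambda s: s.position)
        positions[chrom] = np.array([s.position for s in chrom_sites])
        site_ids[chrom] = [s.site_id for s in chrom_sites]

    by_site: dict[str, list[tuple[int, str]]] = {s.site_id: [] for s in sites}
    unassigned = 0
    for e in ends:
        pos_arr = positions.get(e.chrom)
        if pos_arr is None:
            unassigned += 1
            continue
        i = int(np.searchsorted(pos_arr, e.end_position))
        hit = None
        for j in (i - 1, i):  # candidate sites flanking the insertion point
            if 0 <= j < len(pos_arr):
                d = e.end_position - int(pos_arr[j])
                if -window <= d < window:
                    hit = (site_ids[e.chrom][j], d)
                    break
        if hit is None:
            unassigned += 1
        else:
            side = "right" if e.strand == "+" else "left"
            by_site[hit[0]].append((hit[1], side))
    return AssignedEnds(by_site=by_site, unassigned=unassigned, window=window)


def resection_extent(
    distances: Sequence[float] | np.ndarray,
    quantile: float = DEFAULT_QUANTILE,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> float:
    """Quantile of absolute end-to-cut distances; NaN below min_support.

    A pure maximum would make the extent a single-read statistic; a high
    quantile is robust to stray ends yet tracks the far edge of the signal.
    Monotone in ``quantile`` and exactly equivariant under scaling of the
    distances.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    d = np.abs(np.asarray(distances, dtype=float))
    if d.size < min_support:
        return float("nan")
    return float(np.quantile(d, quantile))


@dataclass
class ResectionProfile:
    """Binned per-side end signal around one cut site, with extent estimates."""

    site_id: str
    window: int
    bin_size: int
    signal: np.ndarray = field(repr=False)  # shape (2, n_bins); rows = left, right
    n_ends: int = 0
    extent_left: float = float("nan")
    extent_right: float = float("nan")

    @property
    def n_bins(self) -> int:
        return self.signal.shape[1]

    @property
    def extent(self) -> float:
        vals = [v for v in (self.extent_left, self.extent_right) if not np.isnan(v)]
        return max(vals) if vals else float("nan")


def build_profiles(
    assigned: AssignedEnds,
    bin_size: int = DEFAULT_BIN_SIZE,
    quantile: float = DEFAULT_QUANTILE,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[ResectionProfile]:
    """Bin assigned ends into per-site, per-side profiles with extents.

    Bins tile [−W, W) left to right; bin index = floor((d + W) / bin_size).
    The per-side bin sums equal the per-side assigned end counts, so the raw
    profile is a lossless summary of binned signal.
    """
    window = assigned.window
    if (2 * window) % bin_size != 0:
        raise ValueError(f"bin_size {bin_size} must divide the full window {2 * window}")
    n_bins = (2 * window) // bin_size
    profiles = []
    for site_id in sorted(assigned.by_site):
        sig = np.zeros((2, n_bins))
        per_side: dict[str, list[int]] = {"left": [], "right": []}
        for d, side in assigned.by_site[site_id]:
            sig[SIDES.index(side), (d + window) // bin_size] += 1
            per_side[side].append(d)
        profiles.append(
            ResectionProfile(
                site_id=site_id,
                window=window,
                bin_size=bin_size,
                signal=sig,
                n_ends=len(assigned.by_site[site_id]),
                extent_left=resection_extent(per_side["left"], quantile, min_support),
                extent_right=resection_extent(per_side["right"], quantile, min_support),
            )
        )
    return profiles


def heatmap_matrix(
    profiles: Sequence[ResectionProfile],
    normalize: str = "raw",
    sort: str = "total_signal",
) -> pd.DataFrame:
    """Sites × bins signal matrix for genome-wide heatmaps.

    Rows are sites sorted descending by total signal or extent (NaN extents
    last), ties broken by site_id; columns are bin left edges relative to
    the cut.  ``per_million`` divides by (total assigned ends / 1e6), so the
    matrix sums to 1e6 when every end was assigned.
    """
    if not profiles:
        raise ValueError("no profiles")
    if normalize not in ("raw", "per_million"):
        raise ValueError(f"unknown normalize {normalize!r}")
    if sort not in ("total_signal", "extent"):
        raise ValueError(f"unknown sort {sort!r}")
    window, bin_size = profiles[0].window, profiles[0].bin_size
    for p in profiles:
        if p.window != window or p.bin_size != bin_size:
            raise ValueError(
                f"profile {p.site_id!r} has window/bin ({p.window}, {p.bin_size}); "
                f"expected ({window}, {bin_size})"
            )
    if sort == "total_signal":
        key = lambda p: (-p.n_ends, p.site_id)
    else:
        key = lambda p: (-(p.extent if not np.isnan(p.extent) else -np.inf), p.site_id)
    ordered = sorted(profiles, key=key)
    mat = np.vstack([p.signal.sum(axis=0) for p in ordered])
    if normalize == "per_million":
        total = sum(p.n_ends for p in profiles)
        if total > 0:
            mat = mat / (total / 1e6)
    cols = np.arange(-window, window, bin_size)
    return pd.DataFrame(mat, index=pd.Index([p.site_id for p in ordered], name="site_id"), columns=cols)


def compare_genotypes(
    profiles_a: Sequence[ResectionProfile],
    profiles_b: Sequence[ResectionProfile],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-site extent deltas (B − A) and aggregate medians for two genotypes.

    The canonical use is an end-joining-deficient control (protected ends)
    against a resection-proficient mutant; both inputs must cover the same
    site set.
    """
    a_map = {p.site_id: p for p in profiles_a}
    b_map = {p.site_id: p for p in profiles_b}
    only_a = sorted(set(a_map) - set(b_map))
    only_b = sorted(set(b_map) - set(a_map))
    if only_a or only_b:
        raise ValueError(
            f"site sets differ: only in A {only_a[:5]}, only in B {only_b[:5]}"
        )
    rows = []
    for site_id in sorted(a_map):
        ea, eb = a_map[site_id].extent, b_map[site_id].extent
        rows.append(
            {
                "site_id": site_id,
                "extent_a": ea,
                "extent_b": eb,
                "delta_extent": eb - ea,
                "n_ends_a": a_map[site_id].n_ends,
                "n_ends_b": b_map[site_id].n_ends,
            }
        )
    table = pd.DataFrame(rows).set_index("site_id")
    summary = {
        "median_extent_a": float(np.nanmedian(table["extent_a"])) if len(table) else float("nan"),
        "median_extent_b": float(np.nanmedian(table["extent_b"])) if len(table) else float("nan"),
        "median_delta": float(np.nanmedian(table["delta_extent"])) if len(table) else float("nan"),
    }
    return table, summary
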