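"""Independent brute-force oracles and small data builders for the tests.

The oracles deliberately re-derive results by exhaustive search — every
(read, spacer) pair for counting, every (end, site) pair for assignment —
so they share no code path with the implementations they check.
"""

from __future__ import annotations

from pathlib import Path

from dsbscreen.library import LibraryIndex
from dsbscreen.quant import AnchorConfig

# Published per-gene guide spacers for mouse/human end-protection factors
# (all 19-mers), used as realistic fixture records.
KNOWN_GUIDES = [
    ("gTrp53bp1", "Trp53bp1", "GAACCTGTCAGACCCGATC"),
    ("gLin37", "Lin37", "AAGCTATTTGACCGGAGTG"),
    ("gBrca1", "Brca1", "GTCTACATTGAACTAGGTA"),
    ("gCtip", "Ctip", "ATTAACCGGCTACGAAAGA"),
    ("gBard1", "Bard1", "AAATCGTAAAGGCTGCCAC"),
    ("gBlm", "Blm", "GATTTAACGAAGGAATCGG"),
    ("gFancd2", "Fancd2", "TCTTGTGATGTCGCTCGAC"),
    ("gTrp53bp1_h", "TP53BP1", "TCTAGTGTGTTAGATCAGG"),
    ("gLin37_h", "LIN37", "TCTAGGGAGCGTCTGGATG"),
]


def write_library_tsv(path: Path, rows) -> Path:
    lines = ["guide_id\tgene\tspacer"]
    lines += [f"{g}\t{gene}\t{sp}" for g, gene, sp in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_fastq(path: Path, seqs) -> Path:
    with path.open("w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")
    return path


def _naive_anchor(read: str, anchor: str, max_mm: int) -> int | None:
    """Leftmost offset with the minimal mismatch count <= max_mm."""
    best, best_mm = None, max_mm + 1
    for i in range(len(read) - len(anchor) + 1):
        mm = sum(1 for a, b in zip(read[i : i + len(anchor)], anchor) if a != b)
        if mm < best_mm:
            best, best_mm = i, mm
    return best


def oracle_count(
    reads_by_sample: dict[str, list[str]],
    index: LibraryIndex,
    cfg: AnchorConfig,
    ambiguous_policy: str,
):
    """Brute-force counter: every library spacer tried against every read.

    Restricted to the anchor-defined window (the bases following the best
    anchor occurrence), per the fixed amplicon layout.  Only supports
    libraries with a single spacer length (all test instances comply).
    """
    lengths = {len(s) for s in index.spacer_map}
    assert len(lengths) == 1, "oracle assumes a fixed-length spacer library"
    (length,) = lengths
    lo, hi = cfg.spacer_length_range
    assert lo == hi == length

    counts_by_sample: dict[str, dict[str, float]] = {}
    qc_all = {}
    for sample, reads in reads_by_sample.items():
        qc = {k: 0.0 for k in (
            "total_reads", "extracted", "no_anchor", "bad_length", "matched",
            "unmatched_spacer", "ambiguous_assigned", "ambiguous_discarded")}
        sample_counts = {g.guide_id: 0.0 for g in index.records}
        for read in reads:
            read = read.upper()
            qc["total_reads"] += 1
            if len(read) < len(cfg.anchor5) + lo:
                qc["no_anchor"] += 1
                continue
            pos = _naive_anchor(read, cfg.anchor5, cfg.max_anchor_mismatches)
            if pos is None:
                qc["no_anchor"] += 1
                continue
            window = read[pos + len(cfg.anchor5) : pos + len(cfg.anchor5) + hi]
            if len(window) < lo:
                qc["bad_length"] += 1
                continue
            qc["extracted"] += 1
            hit_guides: list[str] = []
            for spacer, guide_ids in index.spacer_map.items():
                if window[: len(spacer)] == spacer:
                    hit_guides.extend(guide_ids)
            if not hit_guides:
                qc["unmatched_spacer"] += 1
            elif len(hit_guides) == 1:
                qc["matched"] += 1
                sample_counts[hit_guides[0]] += 1
            elif ambiguous_policy == "discard":
                qc["ambiguous_discarded"] += 1
            else:
                qc["matched"] += 1
                qc["ambiguous_assigned"] += 1
                for g in hit_guides:
                    sample_counts[g] += 1.0 / len(hit_guides)
        qc_all[sample] = qc
        counts_by_sample[sample] = sample_counts
    return counts_by_sample, qc_all


def oracle_assign(ends, sites, window):
    """Brute-force end assignment: test every (end, site) pair."""
    by_site = {s.site_id: [] for s in sites}
    unassigned = 0
    for e in ends:
        hits = [
            s for s in sites
            if s.chrom == e.chrom and -window <= e.end_position - s.position < window
        ]
        assert len(hits) <= 1, "overlapping windows in oracle input"
        if not hits:
            unassigned += 1
        else:
            site = hits[0]
            side = "right" if e.strand == "+" else "left"
            by_site[site.site_id].append((e.end_position - site.position, side))
    return by_site, unassigned
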