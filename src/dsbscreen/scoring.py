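"""Reads-per-million normalization, per-guide enrichment, gene ranking.

Normalization follows the screen's printed rule: each guide's reads are
divided by the sample's total guide reads, scaled to a million, and offset
by a pseudocount of one,

    normalized = (reads_per_guide / total_reads_in_sample) * 1e6 + 1

so that unobserved guides sit exactly at 1 and every ratio is finite.  The
enrichment score of a guide is the ratio of its normalized abundance in two
samples (sorted RPA-high over RPA-low by convention); genes are ranked by a
robust summary of their guides' scores.  No variance model or p-value is
attached: the screen ranks by fold enrichment alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import LibraryIndex
from .quant import CountTable

__all__ = [
    "SCALE",
    "PSEUDOCOUNT",
    "NormalizedTable",
    "EnrichmentTable",
    "normalize",
    "enrichment",
    "rank_genes",
    "screen_report",
]

SCALE = 1_000_000.0
PSEUDOCOUNT = 1.0

GENE_STATISTICS = ("median", "second_best", "count_above")


@dataclass
class NormalizedTable:
    """Per-guide normalized abundances (>= 1) and per-sample library sizes."""

    normalized: pd.DataFrame
    library_size: pd.Series
    genes: pd.Series = field(repr=False)

    @property
    def samples(self) -> list[str]:
        return list(self.normalized.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.normalized.copy()
        out.insert(0, "gene", self.genes)
        out.to_csv(path, sep="\t", index_label="guide_id", float_format="%.10g")


@dataclass
class EnrichmentTable:
    """Per-guide enrichment scores for one (numerator, denominator) pair."""

    numerator_sample: str
    denominator_sample: str
    table: pd.DataFrame  # columns: gene, norm_num, norm_den, score

    @property
    def score(self) -> pd.Series:
        return self.table["score"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="guide_id", float_format="%.10g")


def normalize(counts: CountTable | pd.DataFrame) -> NormalizedTable:
    """Apply the per-million pseudocount normalization to raw counts.

    Raises ``ValueError`` naming any sample whose total count is zero — the
    normalized value is undefined there.
    """
    if isinstance(counts, CountTable):
        df, genes = counts.counts, counts.genes
    else:
        df = counts
        genes = pd.Series("", index=df.index, name="gene")
    library_size = df.sum(axis=0)
    zero = library_size[library_size == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total reads: {list(zero.index)}; "
            "normalization is undefined"
        )
    normalized = df.div(library_size, axis=1) * SCALE + PSEUDOCOUNT
    return NormalizedTable(normalized=normalized, library_size=library_size, genes=genes)


def enrichment(norm: NormalizedTable, numerator: str, denominator: str) -> EnrichmentTable:
    """Per-guide ratio of normalized abundances, numerator / denominator."""
    for name in (numerator, denominator):
        if name not in norm.normalized.columns:
            raise ValueError(f"unknown sample {name!r}; have {norm.samples}")
    num = norm.normalized[numerator]
    den = norm.normalized[denominator]
    table = pd.DataFrame(
        {
            "gene": norm.genes,
            "norm_num": num,
            "norm_den": den,
            "score": num / den,
        },
        index=norm.normalized.index,
    )
    return EnrichmentTable(numerator_sample=numerator, denominator_sample=denominator, table=table)


def _second_best(scores: np.ndarray) -> float:
    s = np.sort(scores)[::-1]
    return float(s[1]) if len(s) > 1 else float(s[0])


def rank_genes(
    enr: EnrichmentTable,
    index: LibraryIndex,
    statistic: str = "median",
    threshold: float = 4.0,
) -> pd.DataFrame:
    """Summarize guide scores per gene and rank genes by one statistic.

    ``median`` (default) is robust to a single noisy guide; ``second_best``
    demands at least two supporting guides; ``count_above`` counts guides
    over ``threshold``.  Ranking is descending with lexicographic gene-name
    tie-break, so output order is deterministic.
    """
    if statistic not in GENE_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {GENE_STATISTICS}")
    lib_genes = {r.guide_id: r.gene for r in index.records}
    missing = [g for g in enr.table.index if g not in lib_genes]
    if missing:
        raise ValueError(f"guide(s) scored but absent from library: {missing[:5]}")
    lib_guides_per_gene = pd.Series([r.gene for r in index.records]).value_counts()

    rows = []
    for gene, sub in enr.table.groupby("gene", sort=True):
        scores = sub["score"].to_numpy()
        rows.append(
            {
                "gene": gene,
                "n_guides": int(lib_guides_per_gene.get(gene, 0)),
                "median_score": float(np.median(scores)),
                "second_best": _second_best(scores),
                "max_score": float(scores.max()),
                "n_above_threshold": int((scores > threshold).sum()),
                "guide_scores": ",".join(f"{s:.6g}" for s in np.sort(scores)[::-1]),
            }
        )
    columns = [
        "gene",
        "n_guides",
        "median_score",
        "second_best",
        "max_score",
        "n_above_threshold",
        "guide_scores",
    ]
    summary = pd.DataFrame(rows, columns=columns).set_index("gene")
    stat_col = {
        "median": "median_score",
        "second_best": "second_best",
        "count_above": "n_above_threshold",
    }[statistic]
    summary = summary.sort_values(
        by=[stat_col, "gene"], ascending=[False, True], kind="mergesort"
    )
    summary["rank"] = np.arange(1, len(summary) + 1)
    summary.attrs["statistic"] = statistic
    summary.attrs["threshold"] = threshold
    return summary


def screen_report(
    counts: CountTable,
    norm: NormalizedTable,
    enr: EnrichmentTable,
    summary: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the result bundle: normalized, per-guide scores, gene summary, QC.

    Inputs must agree on guides and samples; reruns on identical inputs
    produce byte-identical files (floats printed at fixed precision).
    """
    guides = list(counts.counts.index)
    if list(norm.normalized.index) != guides or list(enr.table.index) != guides:
        raise ValueError("inconsistent guide sets between counts, normalized and enrichment tables")
    for name in (enr.numerator_sample, enr.denominator_sample):
        if name not in counts.samples:
            raise ValueError(f"enrichment sample {name!r} missing from counts")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "normalized": out_dir / "normalized.tsv",
        "grna_scores": out_dir / "grna_scores.tsv",
        "gene_summary": out_dir / "gene_summary.tsv",
        "qc": out_dir / "qc.json",
    }
    norm.to_tsv(paths["normalized"])
    enr.to_tsv(paths["grna_scores"])
    summary.to_csv(paths["gene_summary"], sep="\t", float_format="%.10g")
    qc_payload = {
        "samples": counts.samples,
        "numerator_sample": enr.numerator_sample,
        "denominator_sample": enr.denominator_sample,
        "library_size": {k: float(v) for k, v in norm.library_size.items()},
        "per_sample_qc": counts.qc,
        "gene_statistic": summary.attrs.get("statistic", "median"),
    }
    paths["qc"].write_text(json.dumps(qc_payload, indent=2, sort_keys=True) + "\n")
    return paths
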