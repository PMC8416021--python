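"""Normalization formula, enrichment algebra, gene ranking and reports."""

import numpy as np
import pandas as pd
import pytest

from dsbscreen.library import GuideRecord, build_index
from dsbscreen.quant import CountTable
from dsbscreen.scoring import (
    enrichment,
    normalize,
    rank_genes,
    screen_report,
)


def make_counts(data: dict[str, dict[str, float]], genes: dict[str, str] | None = None):
    df = pd.DataFrame(data, dtype=float)
    df.index.name = "guide_id"
    if genes is None:
        genes = {g: f"gene_{g}" for g in df.index}
    qc = {s: {"total_reads": float(df[s].sum())} for s in df.columns}
    return CountTable(counts=df, genes=pd.Series(genes, name="gene").loc[df.index], qc=qc)


def index_for(counts: CountTable):
    recs = []
    bases = "ACGT"
    for i, g in enumerate(counts.counts.index):
        code = np.base_repr(i, base=4).zfill(10)
        recs.append(GuideRecord(g, counts.genes[g], "".join(bases[int(c)] for c in code) + "A" * 9))
    return build_index(recs)


def test_printed_formula_arithmetic():
    """250 reads in a 500,000-read sample -> (250/5e5)*1e6 + 1 = 501."""
    counts = make_counts({"s": {"g1": 250, "g2": 499_750}})
    norm = normalize(counts)
    assert norm.normalized.loc["g1", "s"] == 501.0
    assert norm.library_size["s"] == 500_000


def test_zero_count_guide_floors_at_one():
    counts = make_counts({"s": {"g1": 0, "g2": 100}})
    assert normalize(counts).normalized.loc["g1", "s"] == 1.0


def test_normalization_conserves_one_million():
    rng = np.random.default_rng(7)
    raw = {f"g{i}": float(c) for i, c in enumerate(rng.integers(0, 5000, size=400))}
    counts = make_counts({"a": raw, "b": {k: v * 3 + 1 for k, v in raw.items()}})
    norm = normalize(counts)
    for s in ("a", "b"):
        total = (norm.normalized[s] - 1.0).sum()
        assert total == pytest.approx(1e6, rel=1e-6)
        assert (norm.normalized[s] >= 1.0).all()


def test_zero_total_sample_is_an_error():
    counts = make_counts({"ok": {"g1": 5, "g2": 5}, "void": {"g1": 0, "g2": 0}})
    with pytest.raises(ValueError, match="void"):
        normalize(counts)


def test_enrichment_ratio_and_pseudocount_identity():
    counts = make_counts({"high": {"g1": 250, "g2": 499_750, "g3": 0},
                          "low": {"g1": 0, "g2": 500_000, "g3": 0}})
    enr = enrichment(normalize(counts), "high", "low")
    assert enr.table.loc["g1", "score"] == 501.0  # 501 / 1
    assert enr.table.loc["g3", "score"] == 1.0    # unobserved in both: 1/1
    with pytest.raises(ValueError, match="unknown sample"):
        enrichment(normalize(counts), "high", "unsorted")


def test_equal_abundance_scores_one():
    counts = make_counts({"a": {"g1": 100, "g2": 300}, "b": {"g1": 100, "g2": 300}})
    enr = enrichment(normalize(counts), "a", "b")
    assert (enr.table["score"] == 1.0).all()


def test_antisymmetry_at_roundoff_precision():
    """enrichment(a,b) x enrichment(b,a) = 1 up to double round-off."""
    rng = np.random.default_rng(11)
    raw = {f"g{i}": float(c) for i, c in enumerate(rng.integers(0, 900, size=500))}
    raw2 = {f"g{i}": float(c) for i, c in enumerate(rng.integers(0, 900, size=500))}
    counts = make_counts({"a": raw, "b": raw2})
    norm = normalize(counts)
    fwd = enrichment(norm, "a", "b").table["score"]
    rev = enrichment(norm, "b", "a").table["score"]
    prod = (fwd * rev).to_numpy()
    assert np.all(np.abs(prod - 1.0) <= 4 * np.finfo(float).eps)
    assert np.all(np.isfinite(fwd)) and (fwd > 0).all()


def test_scale_invariance_in_large_count_limit():
    """Multiplying one sample's raw counts by k=10 moves every score <2%
    when all counts are >=100 (the pseudocount becomes negligible)."""
    rng = np.random.default_rng(3)
    raw = {f"g{i}": float(c) for i, c in enumerate(rng.integers(100, 5000, size=300))}
    rawb = {f"g{i}": float(c) for i, c in enumerate(rng.integers(100, 5000, size=300))}
    base = make_counts({"a": raw, "b": rawb})
    scaled = make_counts({"a": raw, "b": {k: 10 * v for k, v in rawb.items()}})
    s0 = enrichment(normalize(base), "a", "b").table["score"]
    s1 = enrichment(normalize(scaled), "a", "b").table["score"]
    assert np.all(np.abs(s1 / s0 - 1.0) < 0.02)


def _enr_from_scores(gene_scores: dict[str, list[float]]):
    counts_high, counts_low, genes = {}, {}, {}
    for gene, scores in gene_scores.items():
        for j, sc in enumerate(scores):
            gid = f"{gene}_sg{j}"
            genes[gid] = gene
            counts_low[gid] = 1000.0
            counts_high[gid] = 1000.0 * sc
    counts = make_counts({"high": counts_high, "low": counts_low}, genes)
    return counts, enrichment(normalize(counts), "high", "low")


def test_dominant_gene_ranks_first_under_every_statistic():
    gene_scores = {"geneA": [8.0] * 5}
    gene_scores.update({f"gene{chr(66 + i)}": [1.0] * 5 for i in range(5)})
    counts, enr = _enr_from_scores(gene_scores)
    index = index_for(counts)
    for stat in ("median", "second_best", "count_above"):
        summary = rank_genes(enr, index, statistic=stat)
        assert summary.index[0] == "geneA" and summary["rank"].iloc[0] == 1


def test_second_best_statistic_prefers_consistent_support():
    counts, enr = _enr_from_scores(
        {"flashy": [8.0, 1.0, 1.0, 1.0, 1.0], "steady": [3.0, 3.0, 3.0, 3.0, 3.0]}
    )
    index = index_for(counts)
    summary = rank_genes(enr, index, statistic="second_best")
    assert summary.index[0] == "steady"
    # scores share the library-size factor, so their ratio is the planted 3:1
    # up to the pseudocount offset
    ratio = summary.loc["steady", "second_best"] / summary.loc["flashy", "second_best"]
    assert ratio == pytest.approx(3.0, rel=1e-3)


def test_rank_ties_break_lexicographically():
    counts, enr = _enr_from_scores({"zeta": [2.0] * 3, "alpha": [2.0] * 3})
    summary = rank_genes(enr, index_for(counts))
    assert list(summary.index[:2]) == ["alpha", "zeta"]
    assert sorted(summary["rank"]) == list(range(1, len(summary) + 1))


def test_scored_guide_missing_from_library_is_an_error():
    counts, enr = _enr_from_scores({"geneA": [2.0, 2.0]})
    stranger = build_index([GuideRecord("other", "geneB", "A" * 19)])
    with pytest.raises(ValueError, match="absent from library"):
        rank_genes(enr, stranger)


def test_report_bundle_is_deterministic_and_complete(tmp_path):
    counts, enr = _enr_from_scores({"geneA": [4.0, 5.0], "geneB": [1.0, 1.0]})
    norm = normalize(counts)
    summary = rank_genes(enr, index_for(counts))
    p1 = screen_report(counts, norm, enr, summary, tmp_path / "r1")
    p2 = screen_report(counts, norm, enr, summary, tmp_path / "r2")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()
    scores = pd.read_csv(p1["grna_scores"], sep="\t")
    assert len(scores) == len(counts.counts)


def test_report_rejects_inconsistent_guides(tmp_path):
    counts, enr = _enr_from_scores({"geneA": [4.0, 5.0]})
    norm = normalize(counts)
    summary = rank_genes(enr, index_for(counts))
    enr.table = enr.table.iloc[:-1]
    with pytest.raises(ValueError, match="inconsistent"):
        screen_report(counts, norm, enr, summary, tmp_path / "bad")


def test_empty_enrichment_reports_headers_only(tmp_path):
    counts = make_counts({"a": {}, "b": {}})
    counts.counts = counts.counts.astype(float)
    # normalization is undefined on empty samples; build tables directly
    from dsbscreen.scoring import EnrichmentTable, NormalizedTable

    empty = pd.DataFrame(columns=["a", "b"], index=pd.Index([], name="guide_id"), dtype=float)
    genes = pd.Series([], dtype=object, name="gene")
    norm = NormalizedTable(normalized=empty, library_size=pd.Series({"a": 1.0, "b": 1.0}), genes=genes)
    enr = EnrichmentTable("a", "b", pd.DataFrame(
        columns=["gene", "norm_num", "norm_den", "score"],
        index=pd.Index([], name="guide_id")))
    summary = rank_genes(enr, build_index([GuideRecord("g", "x", "A" * 19)]))
    counts.counts = empty.copy()
    counts.genes = genes
    paths = screen_report(counts, norm, enr, summary, tmp_path / "empty")
    lines = paths["grna_scores"].read_text().splitlines()
    assert lines[0].startswith("guide_id") and len(lines) == 1
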