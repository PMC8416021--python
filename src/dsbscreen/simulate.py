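"""Synthetic data generators for the screen and End-seq pipelines.

Two generators produce inputs with the statistical structure the analysis
assumes, plus a truth table sufficient to score recovery:

* ``simulate_screen`` emulates a FACS-sorted pooled CRISPR screen: guide
  abundances are log-normal, sorted populations are multinomial draws from
  the abundance vector, and planting a per-gene fold change in one
  population models selection of that gene's knockouts into a sort gate.
  Reads are the fixed vector context around each spacer with i.i.d.
  substitution errors, written as plain FASTQ.

* ``simulate_endseq`` emulates strand-aware break-end records around
  well-separated cut sites on a synthetic chromosome, with one tract-length
  distribution per genotype: ``protected`` ends stay within a short uniform
  tract (end joining-proficient control), ``resected`` tracts are
  exponential, truncated at a hard cap (resection-proficient mutant).

Everything is deterministic given (config, seed): identical inputs give
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .endseq import CutSite, EndAlignment, write_ends_bed, write_sites_bed
from .library import GuideRecord, LibraryIndex, build_index, write_library
from .quant import DEFAULT_ANCHOR3, DEFAULT_ANCHOR5

__all__ = [
    "ScreenSimConfig",
    "EndseqSimConfig",
    "ScreenSim",
    "EndseqSim",
    "simulate_screen",
    "simulate_endseq",
    "random_spacers",
    "build_read",
    "write_fastq",
    "default_planted_hits",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def default_planted_hits(n: int = 6, fold: float = 8.0) -> dict[str, float]:
    """The default planted-hit set: the first ``n`` genes at ``fold``-x."""
    return {f"gene{i:04d}": fold for i in range(1, n + 1)}


@dataclass
class ScreenSimConfig:
    """Study conditions for the sorted-screen simulation.

    Defaults are desk scale — 120 genes x 5 guides, 2e5 reads per sample,
    six genes planted at 8-fold in the RPA-high gate — small enough to run
    the whole pipeline in seconds yet large enough for sampling noise to
    matter.  ``planted_hits_low`` supports the mirrored design where hits
    deplete resection capacity and surface in the low gate.
    """

    n_genes: int = 120
    guides_per_gene: int = 5
    sigma: float = 1.0  # log-normal spread of baseline guide abundance
    planted_hits: dict[str, float] | None = None  # gene -> fold in "high"
    planted_hits_low: dict[str, float] = field(default_factory=dict)
    reads_per_sample: int = 200_000
    error_rate: float = 0.001  # i.i.d. per-base substitution probability
    anchor5: str = DEFAULT_ANCHOR5
    anchor3: str = DEFAULT_ANCHOR3
    spacer_length: int = 19
    read_length: int = 50
    samples: tuple[str, ...] = ("high", "low", "unsorted")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_hits is None:
            self.planted_hits = default_planted_hits()
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.spacer_length < 1:
            raise ValueError("spacer_length must be >= 1")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("samples must be unique")
        genes = set(self.gene_names())
        for mapping, name in ((self.planted_hits, "planted_hits"),
                              (self.planted_hits_low, "planted_hits_low")):
            for gene, fold in mapping.items():
                if gene not in genes:
                    raise ValueError(f"{name}: unknown gene {gene!r}")
                if fold <= 0:
                    raise ValueError(f"{name}: fold_change for {gene!r} must be > 0")

    def gene_names(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass
class ScreenSim:
    """Simulation outputs: file paths, library index and the truth table."""

    library: LibraryIndex
    fastq_paths: dict[str, Path]
    library_path: Path
    truth_path: Path
    truth: pd.DataFrame


def random_spacers(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """``n`` distinct random DNA ``length``-mers (rejection sampling)."""
    if n > 4**length:
        raise ValueError(f"cannot draw {n} distinct {length}-mers")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            s = _BASES[row].tobytes().decode()
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def build_read(spacer: str, cfg: ScreenSimConfig) -> str:
    """Error-free read layout: anchor5 + spacer + anchor3, padded/truncated."""
    read = cfg.anchor5 + spacer + cfg.anchor3
    if len(read) < cfg.read_length:
        read += "A" * (cfg.read_length - len(read))
    return read[: cfg.read_length]


def _apply_errors(read: str, n_errors: int, rng: np.random.Generator) -> str:
    arr = list(read)
    positions = rng.choice(len(arr), size=n_errors, replace=False)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alternatives[rng.integers(0, 3)]
    return "".join(arr)


def write_fastq(path: Path, reads: list[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as plain FASTQ with constant quality."""
    with path.open("w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_screen(cfg: ScreenSimConfig, out_dir: str | Path) -> ScreenSim:
    """Generate library TSV, per-sample FASTQ and a truth table.

    Per-sample guide probabilities are the log-normal baseline, multiplied
    by each planted gene's fold change in the relevant gate and
    renormalized; read counts per guide are one multinomial draw of
    ``reads_per_sample``.  Sorting is modelled at the abundance level, not
    by simulating per-cell fluorescence.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = cfg.gene_names()
    guide_ids = [f"{g}_sg{j}" for g in genes for j in range(1, cfg.guides_per_gene + 1)]
    guide_genes = [g for g in genes for _ in range(cfg.guides_per_gene)]
    n_guides = len(guide_ids)
    spacers = random_spacers(n_guides, cfg.spacer_length, rng)

    records = [
        GuideRecord(gid, gene, sp) for gid, gene, sp in zip(guide_ids, guide_genes, spacers)
    ]
    index = build_index(records)
    library_path = out_dir / "library.tsv"
    write_library(index, library_path)

    baseline = rng.lognormal(mean=0.0, sigma=cfg.sigma, size=n_guides)
    baseline /= baseline.sum()

    fold_by_sample: dict[str, np.ndarray] = {}
    probs: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for sample in cfg.samples:
        fold = np.ones(n_guides)
        planted = cfg.planted_hits if sample == "high" else (
            cfg.planted_hits_low if sample == "low" else {}
        )
        for i, gene in enumerate(guide_genes):
            if gene in planted:
                fold[i] = planted[gene]
        p = baseline * fold
        p /= p.sum()
        fold_by_sample[sample] = fold
        probs[sample] = p
        counts[sample] = rng.multinomial(cfg.reads_per_sample, p)

    templates = [build_read(sp, cfg) for sp in spacers]
    fastq_paths: dict[str, Path] = {}
    for sample in cfg.samples:
        order = np.repeat(np.arange(n_guides), counts[sample])
        rng.shuffle(order)
        n_err = rng.binomial(cfg.read_length, cfg.error_rate, size=len(order))
        reads = []
        for r, (gi, k) in enumerate(zip(order, n_err)):
            seq = templates[gi]
            if k:
                seq = _apply_errors(seq, int(k), rng)
            reads.append((f"{sample}_read{r + 1}", seq))
        path = out_dir / f"{sample}.fastq"
        write_fastq(path, reads)
        fastq_paths[sample] = path

    truth = pd.DataFrame({"guide_id": guide_ids, "gene": guide_genes, "spacer": spacers})
    for sample in cfg.samples:
        truth[f"p_{sample}"] = probs[sample]
        truth[f"fold_{sample}"] = fold_by_sample[sample]
        truth[f"count_{sample}"] = counts[sample]
    truth["planted"] = [g in cfg.planted_hits or g in cfg.planted_hits_low for g in guide_genes]
    truth_path = out_dir / "truth.tsv"
    truth.set_index("guide_id").to_csv(truth_path, sep="\t", float_format="%.10g")

    return ScreenSim(
        library=index,
        fastq_paths=fastq_paths,
        library_path=library_path,
        truth_path=truth_path,
        truth=truth.set_index("guide_id"),
    )


@dataclass
class EndseqSimConfig:
    """Study conditions for the break-end simulation.

    The ``protected`` genotype draws tract lengths uniformly below
    ``protected_max`` (default 150 bp, under the 200 bp ceiling of a
    joining-proficient control); ``resected`` draws exponential tracts of
    mean ``resected_mean`` hard-truncated at ``resected_cap`` (default
    2 kb).  ``background_rate`` is the fraction of ends falling uniformly
    anywhere in the window with random strand.
    """

    n_sites: int = 200
    ends_per_site: int = 200
    genotype: str = "protected"  # or "resected"
    protected_max: int = 150
    resected_mean: float = 600.0
    resected_cap: int = 2000
    background_rate: float = 0.0
    window: int = 5000
    site_spacing: int = 11_000
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in ("protected", "resected"):
            raise ValueError(f"genotype must be 'protected' or 'resected', got {self.genotype!r}")
        if self.n_sites < 1 or self.ends_per_site < 0:
            raise ValueError("n_sites must be >= 1 and ends_per_site >= 0")
        if self.resected_cap > self.window:
            raise ValueError("resected_cap must be <= window")
        if not self.protected_max < self.resected_cap:
            raise ValueError("protected_max must be < resected_cap")
        if self.site_spacing < 2 * self.window:
            raise ValueError(
                f"site_spacing {self.site_spacing} < 2 x window ({2 * self.window}): "
                "site windows would overlap"
            )
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must be in [0, 1)")

    def true_tract_quantile(self, q: float = 0.95) -> float:
        """Closed-form quantile of the genotype's tract-length distribution."""
        if self.genotype == "protected":
            return q * self.protected_max
        m, c = self.resected_mean, self.resected_cap
        mass = 1.0 - math.exp(-c / m)  # truncated-exponential normalizer
        return -m * math.log(1.0 - q * mass)


@dataclass
class EndseqSim:
    sites: list[CutSite]
    ends: list[EndAlignment]
    sites_path: Path
    ends_path: Path
    truth_path: Path
    truth: pd.DataFrame


def _draw_tract(cfg: EndseqSimConfig, rng: np.random.Generator) -> int:
    if cfg.genotype == "protected":
        return int(rng.uniform(0, cfg.protected_max))
    while True:  # rejection sampling = exponential truncated at the cap
        d = rng.exponential(cfg.resected_mean)
        if d <= cfg.resected_cap:
            return int(d)


def simulate_endseq(cfg: EndseqSimConfig, out_dir: str | Path) -> EndseqSim:
    """Generate cut-site BED, strand-aware end BED6 and a truth table.

    Sites sit on one synthetic chromosome, ``site_spacing`` apart.  Each
    signal end picks a side with equal probability, draws a tract length
    from the genotype distribution, and lands at cut + d (right, '+') or
    cut − d (left, '−'); background ends are uniform in the window.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    first = cfg.window + 1000
    sites = [
        CutSite(cfg.chrom, first + i * cfg.site_spacing, f"site{i + 1:04d}")
        for i in range(cfg.n_sites)
    ]
    ends: list[EndAlignment] = []
    for site in sites:
        for _ in range(cfg.ends_per_site):
            if cfg.background_rate and rng.uniform() < cfg.background_rate:
                pos = int(rng.integers(site.position - cfg.window, site.position + cfg.window))
                strand = "+" if rng.uniform() < 0.5 else "-"
            else:
                d = _draw_tract(cfg, rng)
                if rng.uniform() < 0.5:
                    pos, strand = site.position + d, "+"
                else:
                    pos, strand = site.position - d, "-"
            ends.append(EndAlignment(cfg.chrom, pos, strand))

    sites_path = out_dir / "sites.bed"
    ends_path = out_dir / "ends.bed"
    write_sites_bed(sites, sites_path)
    write_ends_bed(ends, ends_path)

    truth = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "cut_position": [s.position for s in sites],
            "genotype": cfg.genotype,
            "ends_per_site": cfg.ends_per_site,
            "true_p95_tract": cfg.true_tract_quantile(0.95),
        }
    ).set_index("site_id")
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", float_format="%.10g")

    return EndseqSim(
        sites=sites, ends=ends, sites_path=sites_path, ends_path=ends_path,
        truth_path=truth_path, truth=truth,
    )


def screen_config_to_dict(cfg: ScreenSimConfig) -> dict:
    d = asdict(cfg)
    d["samples"] = list(d["samples"])
    return d
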