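"""Synthetic pooled CRISPR knockout screen generator with ground truth.

Emulates a genome-scale positive-selection resistance screen: a skewed
plasmid library, low-MOI lentiviral infection (Poisson integrations, most
infected cells single-knockout), serial rounds of drug selection acting on
gene knockout state, implantation and metastasis bottlenecks (sampling
without replacement, the source of replicate heterogeneity), and negative-
binomial sequencing of each sample.  Every stage keeps full per-guide cell
counts so tests can compare inferred hits against realized truth rather
than against nominal parameters.

Stage lineage per replicate:
    control_cell -> lenvatinib_cell -> primary_tumor -> lung_metastasis
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .countmatrix import CONDITIONS, CountMatrix
from .library import SgRNALibrary, SgRNARecord

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Screen-design and noise parameters.

    Defaults mirror a scaled-down genome-wide resistance screen: 3 guides
    per gene, 1000 non-targeting controls, MOI 0.3, 400x coverage, three
    rounds of drug selection, two infection replicates, and log-normally
    skewed initial library representation.
    """

    n_genes: int = 100
    guides_per_gene: int = 3
    n_mirnas: int = 0
    guides_per_mirna: int = 4
    n_controls: int = 1000
    spacer_length: int = 20
    moi: float = 0.3
    coverage: int = 400           # infected (mutant-pool) cells per guide
    selection_rounds: int = 3
    n_resistance: int = 5
    resistance_multiplier: float = 4.0
    n_suppressor: int = 0
    suppressor_multiplier: float = 0.3
    # cells surviving the implantation / metastasis bottleneck; None means
    # a fixed fraction (10% / 2%) of the pool at that stage
    bottleneck_primary: int | None = None
    bottleneck_metastasis: int | None = None
    n_replicates: int = 2
    seq_depth: float = 500.0      # mean reads per guide
    nb_dispersion: float = 0.01
    error_rate: float = 0.0       # per-base substitution rate in reads
    library_sigma: float = 0.5    # log-normal skew of initial representation
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.guides_per_gene, self.coverage) <= 0:
            raise ValueError("sizes must be positive")
        if self.moi <= 0:
            raise ValueError("moi must be > 0")
        if self.resistance_multiplier <= 0 or self.suppressor_multiplier <= 0:
            raise ValueError("fitness multipliers must be > 0")

    @property
    def n_guides(self) -> int:
        return (
            self.n_genes * self.guides_per_gene
            + self.n_mirnas * self.guides_per_mirna
            + self.n_controls
        )


def _random_spacers(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Distinct random ACGT spacers (collisions re-drawn)."""
    spacers: list[str] = []
    seen: set[str] = set()
    while len(spacers) < n:
        block = _BASES[rng.integers(0, 4, size=(n - len(spacers), length))]
        for row in block:
            s = "".join(row)
            if s not in seen:
                seen.add(s)
                spacers.append(s)
    return spacers


def make_library(cfg: SimConfig, rng: np.random.Generator, name: str = "sim") -> SgRNALibrary:
    """Random annotation table matching the configured design."""
    spacers = _random_spacers(cfg.n_guides, cfg.spacer_length, rng)
    records: list[SgRNARecord] = []
    k = 0
    for g in range(cfg.n_genes):
        gene = f"G{g + 1:04d}"
        for j in range(cfg.guides_per_gene):
            records.append(SgRNARecord(f"{gene}_sg{j + 1}", spacers[k], gene, "gene"))
            k += 1
    for m in range(cfg.n_mirnas):
        mir = f"miR-{m + 1}"
        for j in range(cfg.guides_per_mirna):
            records.append(SgRNARecord(f"{mir}_sg{j + 1}", spacers[k], mir, "miRNA"))
            k += 1
    for c in range(cfg.n_controls):
        ntc = f"NTC_{c + 1:04d}"
        records.append(SgRNARecord(f"{ntc}_sg1", spacers[k], ntc, "non_targeting"))
        k += 1
    return SgRNALibrary(records, spacer_length=cfg.spacer_length, name=name)


@dataclass
class InfectionResult:
    """Per-guide lineage counts after low-MOI infection, with the per-cell
    bookkeeping needed to check the Poisson closed forms."""

    guide_counts: np.ndarray        # lineages per guide
    n_cells: int
    n_infected: int
    n_single_integration: int
    n_integrations: int

    @property
    def infected_fraction(self) -> float:
        return self.n_infected / self.n_cells

    @property
    def single_integration_share(self) -> float:
        return self.n_single_integration / max(self.n_infected, 1)


def simulate_infection(
    cfg: SimConfig,
    rng: np.random.Generator,
    abundance: np.ndarray,
    n_cells: int | None = None,
) -> InfectionResult:
    """Poisson(moi) integrations per exposed cell; every integration of an
    infected cell draws a guide from the library abundance and founds a
    lineage (multi-integration cells contribute one lineage per guide).

    By default enough cells are exposed that the infected pool carries
    ``coverage`` cells per guide, matching how screen coverage is quoted
    (harvested mutant cells over library size)."""
    if n_cells is None:
        p_inf = 1.0 - np.exp(-cfg.moi)
        n_cells = int(round(cfg.coverage * cfg.n_guides / p_inf))
    k = rng.poisson(cfg.moi, size=n_cells)
    n_infected = int((k > 0).sum())
    n_single = int((k == 1).sum())
    n_integrations = int(k.sum())
    p = np.asarray(abundance, dtype=float)
    guide_counts = rng.multinomial(n_integrations, p / p.sum())
    return InfectionResult(guide_counts, n_cells, n_infected, n_single, n_integrations)


def apply_selection(
    population: np.ndarray,
    fitness: np.ndarray,
    rounds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Serial selection at constant population size.

    Each round multiplies expected guide abundance by its fitness
    multiplier and multinomially resamples back to the incoming pool size,
    so a multiplier m enriches geometrically (m^rounds in expectation).
    """
    pop = np.asarray(population, dtype=np.int64)
    size = int(pop.sum())
    if size == 0:
        raise ValueError("population is empty")
    fitness = np.asarray(fitness, dtype=float)
    for _ in range(rounds):
        w = pop * fitness
        total = w.sum()
        if total <= 0:
            raise ValueError("all-zero expected abundance after selection")
        pop = rng.multinomial(size, w / total)
    return pop


def apply_bottleneck(
    population: np.ndarray, size_out: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``size_out`` cells without replacement (engraftment or
    metastatic seeding); guide richness can only shrink."""
    pop = np.asarray(population, dtype=np.int64)
    if size_out <= 0:
        raise ValueError("bottleneck size must be positive")
    total = int(pop.sum())
    if size_out > total:
        raise ValueError(f"bottleneck size {size_out} exceeds population {total}")
    if size_out == total:
        return pop.copy()
    return rng.multivariate_hypergeometric(pop, size_out, method="marginals")


def sequence_counts(
    population: np.ndarray,
    seq_depth: float,
    nb_dispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial read counts with mean proportional to guide
    frequency (gamma-Poisson mixture; dispersion 0 is the Poisson limit)."""
    pop = np.asarray(population, dtype=float)
    if pop.sum() <= 0:
        raise ValueError("cannot sequence an empty population")
    mu = pop / pop.sum() * seq_depth * pop.size
    if nb_dispersion <= 0:
        return rng.poisson(mu)
    lam = np.zeros_like(mu)
    pos = mu > 0
    lam[pos] = rng.gamma(1.0 / nb_dispersion, nb_dispersion * mu[pos])
    return rng.poisson(lam)


def reads_for_counts(
    library: SgRNALibrary,
    counts: np.ndarray,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    read_length: int | None = None,
    shuffle: bool = True,
) -> list[str]:
    """Emit one read per counted molecule: the spacer at offset 0, padded
    with random bases to ``read_length``, with per-base substitutions at
    ``error_rate`` (matches QuantConfig(spacer_offset=0))."""
    L = library.spacer_length
    read_length = read_length or L
    reads: list[str] = []
    for rec, n in zip(library.records, counts):
        reads.extend([rec.spacer] * int(n))
    if read_length > L:
        pad = _BASES[rng.integers(0, 4, size=(len(reads), read_length - L))]
        reads = [r + "".join(p) for r, p in zip(reads, pad)]
    if error_rate > 0 and reads:
        arr = np.frombuffer("".join(reads).encode(), dtype="S1").reshape(
            len(reads), read_length
        ).copy()
        hit = rng.random(arr.shape) < error_rate
        subs = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
        arr[hit] = np.char.encode(subs)
        reads = [row.tobytes().decode() for row in arr]
    if shuffle:
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
    return reads


@dataclass
class SimTruth:
    """Realized ground truth of one simulated screen."""

    sgrna_ids: list[str]
    gene_of_guide: pd.Series          # sgrna_id -> target_id (incl. controls)
    fitness_by_gene: dict[str, float]
    initial_freq: np.ndarray
    stage_cells: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    expected_reads: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def gene_freq(self, stage: str, replicate: str | None = None) -> pd.Series:
        """Realized per-gene cell frequency at a stage (replicate mean)."""
        reps = (
            [replicate]
            if replicate is not None
            else sorted({r for (s, r) in self.stage_cells if s == stage})
        )
        acc = None
        for r in reps:
            cells = self.stage_cells[(stage, r)].astype(float)
            f = pd.Series(cells / cells.sum(), index=self.sgrna_ids)
            g = f.groupby(self.gene_of_guide).sum()
            acc = g if acc is None else acc + g
        return acc / len(reps)

    def gene_enrichment(self, stage: str, baseline: str = "control_cell") -> pd.Series:
        """Realized gene-frequency ratio stage/baseline (pseudo-frequency
        of half a cell guards empty genes)."""
        num = self.gene_freq(stage)
        den = self.gene_freq(baseline)
        eps = 0.5 / max(
            float(self.stage_cells[(baseline, r)].sum())
            for (s, r) in self.stage_cells
            if s == baseline
        )
        return (num + eps) / (den + eps)

    def enriched_genes(self, stage: str, fold: float = 2.0) -> set[str]:
        ratio = self.gene_enrichment(stage)
        targeting = [g for g in ratio.index if g in self.fitness_by_gene]
        return {g for g in targeting if ratio[g] > fold}

    def all_condition_enriched(self, fold: float = 2.0) -> set[str]:
        """Genes enriched (vs control cells) in every drug condition."""
        stages = ("lenvatinib_cell", "primary_tumor", "lung_metastasis")
        sets = [self.enriched_genes(s, fold) for s in stages]
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fitness_by_gene": self.fitness_by_gene,
            "initial_freq": self.initial_freq.tolist(),
            "sgrna_ids": self.sgrna_ids,
            "stage_cells": {
                f"{s}:{r}": c.tolist() for (s, r), c in self.stage_cells.items()
            },
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class ScreenResult:
    library: SgRNALibrary
    counts: CountMatrix
    truth: SimTruth
    reads: dict[str, list[str]] | None = None


def simulate_screen(cfg: SimConfig, emit_reads: bool = False) -> ScreenResult:
    """Run the full screen: library, per-replicate infection, vehicle and
    drug arms, in-vivo bottlenecks, and sequencing of all samples.

    Fully reproducible: identical configs (same seed) give identical
    libraries, counts and truth.
    """
    rng = np.random.default_rng(cfg.seed)
    library = make_library(cfg, rng)
    n = cfg.n_guides

    # gene fitness multipliers under drug; controls and neutral genes at 1
    genes = [f"G{g + 1:04d}" for g in range(cfg.n_genes)]
    special = rng.choice(genes, size=cfg.n_resistance + cfg.n_suppressor, replace=False)
    fitness_by_gene = {g: 1.0 for g in genes}
    for g in special[: cfg.n_resistance]:
        fitness_by_gene[g] = cfg.resistance_multiplier
    for g in special[cfg.n_resistance :]:
        fitness_by_gene[g] = cfg.suppressor_multiplier
    annot = library.guide_target_frame()
    gene_of_guide = annot["target_id"]
    guide_fitness = np.array(
        [fitness_by_gene.get(t, 1.0) for t in gene_of_guide], dtype=float
    )

    # skewed initial representation (plasmid pool)
    initial = rng.lognormal(0.0, cfg.library_sigma, size=n)
    initial /= initial.sum()

    truth = SimTruth(
        sgrna_ids=library.sgrna_ids,
        gene_of_guide=gene_of_guide,
        fitness_by_gene=fitness_by_gene,
        initial_freq=initial,
    )

    neutral = np.ones(n)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    reads: dict[str, list[str]] = {}
    for r in range(cfg.n_replicates):
        rep = f"R{r + 1}"
        pool0 = simulate_infection(cfg, rng, initial).guide_counts

        control = apply_selection(pool0, neutral, cfg.selection_rounds, rng)
        lenva = apply_selection(pool0, guide_fitness, cfg.selection_rounds, rng)

        nb_primary = cfg.bottleneck_primary or max(1, int(0.10 * lenva.sum()))
        seeded = apply_bottleneck(lenva, nb_primary, rng)
        primary = apply_selection(seeded, guide_fitness, 1, rng)

        nb_met = cfg.bottleneck_metastasis or max(1, int(0.02 * primary.sum()))
        seeded_met = apply_bottleneck(primary, nb_met, rng)
        metastasis = apply_selection(seeded_met, guide_fitness, 1, rng)

        for condition, pop in zip(
            CONDITIONS, (control, lenva, primary, metastasis)
        ):
            sample_id = f"{condition}_{rep}"
            truth.stage_cells[(condition, rep)] = pop
            columns[sample_id] = sequence_counts(
                pop, cfg.seq_depth, cfg.nb_dispersion, rng
            )
            meta_rows.append((sample_id, condition, rep))
            if emit_reads:
                reads[sample_id] = reads_for_counts(
                    library, columns[sample_id], rng, error_rate=cfg.error_rate
                )

    counts_df = pd.DataFrame(
        columns, index=pd.Index(library.sgrna_ids, name="sgrna_id"), dtype=np.int64
    )
    meta = pd.DataFrame(
        [(c, rep) for (_s, c, rep) in meta_rows],
        index=pd.Index([s for (s, _c, _r) in meta_rows], name="sample_id"),
        columns=["condition", "replicate"],
    )
    cm = CountMatrix(counts_df, meta)
    return ScreenResult(library, cm, truth, reads or None)


def write_screen(result: ScreenResult, out_dir: str | Path) -> dict[str, Path]:
    """Write library.tsv, counts.tsv, samples.tsv, truth.json (and FASTQ
    per sample when reads were emitted) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "library": out / "library.tsv",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    result.library.to_tsv(paths["library"])
    result.counts.to_tsv(paths["counts"])
    result.counts.meta_to_tsv(paths["samples"])
    result.truth.to_json(paths["truth"])
    if result.reads:
        from .quant import write_fastq

        for sample_id, rds in result.reads.items():
            p = out / f"{sample_id}.fastq"
            write_fastq(p, rds, prefix=sample_id)
            paths[f"fastq:{sample_id}"] = p
    return paths
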