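"""Synthetic pooled-screen generator with selection-bottleneck structure.

Emulates a genome-wide knockout screen under a cytotoxic selection (an
MDM2-antagonist pulse killing 70-85% of cells per round): a mutagenized
cell pool carries one integrated guide per cell; treatment rounds kill
most cells, knockouts that blunt the death pathway survive preferentially,
survivors regrow, and guide abundances are read out by sequencing at two
timepoints per concentration plus an untreated control harvested before
selection.  The default layout is therefore 7 samples: 1 control + 2
timepoints x 3 concentrations.

Ground truth (gene fitness class and per-guide efficiency) is returned
alongside the counts so recovery and calibration of the whole analysis
pipeline can be measured exactly.  All randomness flows from the single
mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    LibraryDesign,
    SampleSheet,
    ScreenFormatError,
    write_count_table,
    write_library_map,
    write_sample_sheet,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_screen",
    "simulate_selection_round",
    "sample_counts",
    "null_config",
]

GENE_CLASSES = ("neutral", "resistant", "essential")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated selection screen.

    Defaults are the desk-scale analogue of the real experiment: 2,000
    genes x 10 guides (the real library is ~18k x ~10), three monotone
    drug doses whose per-round survivor fraction spans the observed
    15-30% band, two selection rounds per timepoint, and sequencing at
    5e6 reads per sample with mild extra-Poisson noise.
    """

    seed: int
    n_genes: int = 2000
    guides_per_gene: int = 10
    prop_neutral: float = 0.875
    prop_resistant: float = 0.025
    prop_essential: float = 0.10
    #: fitness multiplier range of resistant genes under treatment
    resistant_fitness: tuple[float, float] = (2.5, 5.5)
    #: the single strongest resistant gene (the TP53 analogue) gets this
    apex_fitness: float = 8.0
    essential_fitness: float = 0.4
    #: natural-log mean/sd of the baseline guide abundance distribution
    baseline_logabund_mean: float = 0.0
    baseline_logabund_sd: float = 1.0
    #: Beta(a, b) guide-efficiency distribution, most mass near 1
    efficiency_beta: tuple[float, float] = (9.0, 1.0)
    #: sequencing overdispersion (NB variance = mu + phi mu^2)
    phi_seq: float = 0.05
    concentrations_uM: tuple[float, ...] = (14.0, 16.0, 18.0)
    #: per-round survivor fraction at the lowest and highest dose
    survival_range: tuple[float, float] = (0.30, 0.15)
    rounds_per_timepoint: int = 2
    n_timepoints: int = 2
    depth: int = 5_000_000
    population_size: int = 2_000_000

    def __post_init__(self):
        errors = []
        props = self.prop_neutral + self.prop_resistant + self.prop_essential
        if abs(props - 1.0) > 1e-9:
            errors.append(f"class proportions sum to {props}, not 1")
        for s in self.survival_range:
            if not 0 < s <= 1:
                errors.append(f"survival fraction {s} outside (0, 1]")
        if self.depth <= 0:
            errors.append("depth must be > 0")
        if self.population_size <= 0:
            errors.append("population_size must be > 0")
        if self.n_genes < 1 or self.guides_per_gene < 1:
            errors.append("need >= 1 gene and >= 1 guide per gene")
        if not isinstance(self.seed, (int, np.integer)):
            errors.append("seed is mandatory and must be an integer")
        if errors:
            raise ScreenFormatError(errors)

    def survival_at(self, concentration: float) -> float:
        """Per-round survivor fraction of unprotected cells at a dose.

        Linear in concentration between the two ends of ``survival_range``
        (higher dose kills more).
        """
        lo, hi = min(self.concentrations_uM), max(self.concentrations_uM)
        if hi == lo:
            return self.survival_range[0]
        t = (concentration - lo) / (hi - lo)
        return self.survival_range[0] + t * (self.survival_range[1] - self.survival_range[0])


@dataclass(frozen=True)
class SimTruth:
    """Ground truth: per-gene class and fitness, per-guide efficiency."""

    genes: pd.DataFrame  # index gene; columns class, fitness
    guide_efficiency: pd.Series  # index guide id

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        out = self.genes.reset_index().rename(columns={"index": "gene"})
        out.to_csv(path, sep="\t", index=False)

    @property
    def resistant_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["class"] == "resistant"])

    @property
    def apex_gene(self) -> str:
        """The resistant gene with the largest fitness multiplier."""
        res = self.genes[self.genes["class"] == "resistant"]
        if res.empty:
            raise ScreenFormatError(["no resistant genes in this simulation"])
        return res["fitness"].idxmax()


def null_config(seed: int, **overrides) -> SimConfig:
    """All-neutral configuration (no selection signal) for calibration."""
    return SimConfig(
        seed=seed, prop_neutral=1.0, prop_resistant=0.0, prop_essential=0.0, **overrides
    )


def simulate_selection_round(
    abundances: np.ndarray,
    fitness: np.ndarray,
    survival_fraction: float,
    population_size: int,
    rng: np.random.Generator,
    max_retries: int = 3,
) -> np.ndarray:
    """One treatment bottleneck: kill, then regrow (renormalize).

    Each cell carries one guide; a cell with guide fitness f survives with
    probability min(1, survival_fraction x f).  Cells per guide are drawn
    multinomially at ``population_size``, survivors binomially, and the
    surviving pool is renormalized (regrowth is proportional).
    """
    p = np.asarray(abundances, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ScreenFormatError(["abundances must sum to 1"])
    f = np.asarray(fitness, dtype=float)
    if (f <= 0).any():
        raise ScreenFormatError(["fitness multipliers must be > 0"])
    surv_p = np.clip(survival_fraction * f, 0.0, 1.0)
    for _ in range(max_retries):
        cells = rng.multinomial(population_size, p / p.sum())
        survivors = rng.binomial(cells, surv_p)
        total = survivors.sum()
        if total > 0:
            return survivors / total
    raise ScreenFormatError(["no cells survived the selection round after retries"])


def sample_counts(
    abundances: np.ndarray, depth: float, phi_seq: float, rng: np.random.Generator
) -> np.ndarray:
    """Sequencing readout: NB(mu = abundance x depth, phi_seq) per guide.

    phi_seq = 0 degenerates to Poisson; depth 0 gives all zeros.
    """
    p = np.asarray(abundances, dtype=float)
    mu = p * float(depth)
    if depth == 0:
        return np.zeros(p.size, dtype=np.int64)
    if phi_seq <= 0:
        return rng.poisson(mu).astype(np.int64)
    r = 1.0 / phi_seq
    return rng.negative_binomial(r, r / (r + mu)).astype(np.int64)


def _assign_classes(cfg: SimConfig, rng: np.random.Generator):
    n = cfg.n_genes
    n_res = int(round(cfg.prop_resistant * n))
    n_ess = int(round(cfg.prop_essential * n))
    classes = np.array(
        ["resistant"] * n_res + ["essential"] * n_ess + ["neutral"] * (n - n_res - n_ess)
    )
    rng.shuffle(classes)
    fitness = np.ones(n)
    res_idx = np.flatnonzero(classes == "resistant")
    if res_idx.size:
        lo, hi = cfg.resistant_fitness
        fitness[res_idx] = rng.uniform(lo, hi, size=res_idx.size)
        fitness[res_idx[0]] = cfg.apex_fitness  # the TP53 analogue
    fitness[classes == "essential"] = cfg.essential_fitness
    return classes, fitness


def simulate_screen(cfg: SimConfig):
    """Generate one full synthetic screen.

    Returns ``(CountMatrix, SampleSheet, LibraryDesign, SimTruth)``.  The
    control sample is read out from the untreated baseline; each
    concentration then undergoes ``rounds_per_timepoint`` selection rounds
    before each of the two timepoint readouts, with stronger doses killing
    a larger fraction per round.
    """
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    guides = [
        f"{g}_g{j + 1:02d}" for g in genes for j in range(cfg.guides_per_gene)
    ]
    lib = LibraryDesign({gd: gd.rsplit("_", 1)[0] for gd in guides})

    classes, gene_fitness = _assign_classes(cfg, rng)
    a, b = cfg.efficiency_beta
    efficiency = rng.beta(a, b, size=len(guides))
    guide_gene_idx = np.repeat(np.arange(cfg.n_genes), cfg.guides_per_gene)
    # a guide's effect is its gene's effect scaled by its efficiency
    guide_fitness = 1.0 + efficiency * (gene_fitness[guide_gene_idx] - 1.0)

    base = rng.lognormal(cfg.baseline_logabund_mean, cfg.baseline_logabund_sd, len(guides))
    baseline = base / base.sum()

    sample_ids = ["control"]
    sheet_rows = [{"sample_id": "control", "arm": "control", "concentration_uM": 0.0, "timepoint": 0}]
    columns = [sample_counts(baseline, cfg.depth, cfg.phi_seq, rng)]

    for conc in cfg.concentrations_uM:
        surv = cfg.survival_at(conc)
        state = baseline.copy()
        for tp in range(1, cfg.n_timepoints + 1):
            for _ in range(cfg.rounds_per_timepoint):
                state = simulate_selection_round(
                    state, guide_fitness, surv, cfg.population_size, rng
                )
            sid = f"nutlin{conc:g}_t{tp}"
            sample_ids.append(sid)
            sheet_rows.append(
                {"sample_id": sid, "arm": "treated", "concentration_uM": conc, "timepoint": tp}
            )
            columns.append(sample_counts(state, cfg.depth, cfg.phi_seq, rng))

    counts = CountMatrix(tuple(guides), tuple(sample_ids), np.column_stack(columns))
    sheet = SampleSheet(pd.DataFrame(sheet_rows).set_index("sample_id"))
    truth = SimTruth(
        genes=pd.DataFrame({"class": classes, "fitness": gene_fitness}, index=genes),
        guide_efficiency=pd.Series(efficiency, index=guides, name="efficiency"),
    )
    return counts, sheet, lib, truth


def write_simulation(counts, sheet, lib, truth, outdir) -> dict[str, str]:
    """Write the simulated screen in the same TSV dialects the readers use."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "library": outdir / "library.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_count_table(counts, paths["counts"])
    write_library_map(lib, paths["library"])
    write_sample_sheet(sheet, paths["samples"])
    truth.write(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
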