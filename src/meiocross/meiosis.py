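"""Whole-cell meiosis simulation built on the per-SC coarsening model.

A cell carries one bivalent per chromosome.  For genotypes with an intact
synaptonemal complex, crossover-promoting foci are obtained by running the
coarsening dynamics independently on each SC; the per-cell sum of designated
foci is the predicted MLH1 focus count.  The chromatid transmitted to a
gamete inherits each bivalent crossover independently with probability 1/2,
and focus positions on the SC (um) are mapped linearly to genomic positions
(Mb).

For *zyp1* mutants the SC is absent and crossover positions are modelled as
independent: per chromatid and chromosome the CO count is Poisson with a
configurable mean and positions are i.i.d. uniform along the chromosome.

Crossover tables are plain :class:`pandas.DataFrame` objects with columns
``sample, chromosome, position_mb, interval_start_bp, interval_end_bp,
origin`` — the interchange format of every downstream statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coarsening import CoarseningParams, SCState, designate_foci, simulate, simulate_ensemble, init_state

__all__ = [
    "Chromosome",
    "Karyotype",
    "GenotypeSpec",
    "CROSSOVER_COLUMNS",
    "make_crossover_table",
    "validate_crossover_table",
    "poisson_means_from_total",
    "simulate_bivalent_cos",
    "bivalent_to_chromatid",
    "map_sc_to_genome",
    "simulate_zyp1_chromatid",
    "simulate_population",
]

CROSSOVER_COLUMNS = [
    "sample",
    "chromosome",
    "position_mb",
    "interval_start_bp",
    "interval_end_bp",
    "origin",
]


@dataclass(frozen=True)
class Chromosome:
    name: str
    sc_length_um: float
    genomic_length_mb: float

    def __post_init__(self) -> None:
        if self.sc_length_um <= 0 or self.genomic_length_mb <= 0:
            raise ValueError("chromosome lengths must be positive")


@dataclass(frozen=True)
class Karyotype:
    """Ordered set of chromosomes with SC (um) and genomic (Mb) lengths."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if not 1 <= len(names) <= 5:
            raise ValueError("1-5 chromosomes supported")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def scaled(self, sc_factor: float) -> "Karyotype":
        """Same karyotype with every SC length multiplied by ``sc_factor``."""
        return Karyotype(
            tuple(
                Chromosome(c.name, c.sc_length_um * sc_factor, c.genomic_length_mb)
                for c in self.chromosomes
            )
        )

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "Karyotype":
        return cls(
            tuple(
                Chromosome(name, float(v["sc_length_um"]), float(v["genomic_length_mb"]))
                for name, v in d.items()
            )
        )

    def to_dict(self) -> dict:
        return {
            c.name: {"sc_length_um": c.sc_length_um, "genomic_length_mb": c.genomic_length_mb}
            for c in self.chromosomes
        }


@dataclass(frozen=True)
class GenotypeSpec:
    """Simulation parameters of one genotype/sex combination.

    ``dosage_factor`` is the HEI10 dosage factor y of the coarsening model
    (required unless ``zyp1``).  For ``zyp1`` genotypes the coarsening model
    does not apply and ``poisson_means`` gives the mean CO count per
    chromatid for each chromosome.
    """

    name: str
    dosage_factor: float | None = None
    zyp1: bool = False
    sex: str = "female"
    poisson_means: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.zyp1:
            if self.poisson_means is None:
                raise ValueError("zyp1 genotype requires poisson_means")
            if any(v < 0 for v in self.poisson_means.values()):
                raise ValueError("Poisson means must be >= 0")
        else:
            if self.dosage_factor is None or self.dosage_factor <= 0:
                raise ValueError("non-zyp1 genotype requires dosage_factor > 0")


def poisson_means_from_total(total: float, karyotype: Karyotype) -> dict[str, float]:
    """Apportion a total per-chromatid CO mean across chromosomes.

    The share of each chromosome is proportional to its genomic length,
    matching the observed correlation of CO count with chromosome size.
    """
    if total < 0:
        raise ValueError("total mean must be >= 0")
    g = np.array([c.genomic_length_mb for c in karyotype])
    return {c.name: float(total * c.genomic_length_mb / g.sum()) for c in karyotype}


# ---------------------------------------------------------------------------
# crossover tables


def make_crossover_table(rows: Sequence[tuple]) -> pd.DataFrame:
    """Build a crossover table from (sample, chromosome, position_mb[, start, end, origin])."""
    recs = []
    for r in rows:
        r = tuple(r)
        sample, chrom, pos = r[:3]
        start = r[3] if len(r) > 3 else np.nan
        end = r[4] if len(r) > 4 else np.nan
        origin = r[5] if len(r) > 5 else "chromatid"
        recs.append((sample, chrom, float(pos), start, end, origin))
    df = pd.DataFrame(recs, columns=CROSSOVER_COLUMNS)
    return sort_crossover_table(df)


def sort_crossover_table(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["sample", "chromosome", "position_mb"], kind="stable").reset_index(
        drop=True
    )


def validate_crossover_table(df: pd.DataFrame, karyotype: Karyotype | None = None) -> None:
    """Check schema, position bounds and interval sanity; raises ValueError."""
    missing = [c for c in CROSSOVER_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"crossover table missing columns: {missing}")
    if (df["position_mb"] < 0).any():
        raise ValueError("negative CO positions")
    if karyotype is not None:
        for chrom, sub in df.groupby("chromosome"):
            limit = karyotype[str(chrom)].genomic_length_mb
            if (sub["position_mb"] > limit).any():
                raise ValueError(f"CO position beyond the end of {chrom}")
    if {"interval_start_bp", "interval_end_bp"} <= set(df.columns):
        both = df["interval_start_bp"].notna() & df["interval_end_bp"].notna()
        if (df.loc[both, "interval_start_bp"] >= df.loc[both, "interval_end_bp"]).any():
            raise ValueError("interval start must be < end")


# ---------------------------------------------------------------------------
# elementary operations


def simulate_bivalent_cos(
    chromosome: Chromosome,
    genotype: GenotypeSpec,
    params: CoarseningParams,
    rng: np.random.Generator,
    duration: float | None = None,
) -> np.ndarray:
    """Positions (um) of designated crossover foci on one bivalent.

    Runs the full coarsening pipeline — initialization, integration for
    ``duration`` (default ``params.duration``), threshold designation.
    """
    if genotype.zyp1:
        raise ValueError("simulate_bivalent_cos applies only to genotypes with an SC")
    p = params.replace(dosage_factor=genotype.dosage_factor)
    state = init_state(chromosome.sc_length_um, p, rng)
    final = simulate(state, p, duration)
    return np.array([pos for pos, _ in designate_foci(final, p.m_thresh)])


def bivalent_to_chromatid(
    bivalent_cos: np.ndarray, rng: np.random.Generator, p: float = 0.5
) -> np.ndarray:
    """Retain each bivalent CO independently with probability ``p`` (default 1/2)."""
    bivalent_cos = np.asarray(bivalent_cos, dtype=float)
    if bivalent_cos.size == 0:
        return bivalent_cos.copy()
    return bivalent_cos[rng.random(bivalent_cos.size) < p]


def map_sc_to_genome(position, sc_length: float, genomic_length: float):
    """Linear um -> Mb map: position/sc_length * genomic_length."""
    pos = np.asarray(position, dtype=float)
    if np.any(pos < 0) or np.any(pos > sc_length):
        raise ValueError("position outside [0, sc_length]")
    out = pos / sc_length * genomic_length
    return float(out) if out.ndim == 0 else out


def simulate_zyp1_chromatid(
    chromosome: Chromosome, mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Sorted CO positions (Mb) of one chromatid under the *zyp1* null model.

    Count ~ Poisson(mean); positions i.i.d. uniform on the chromosome.
    """
    if mean < 0:
        raise ValueError("Poisson mean must be >= 0")
    n = rng.poisson(mean)
    return np.sort(rng.uniform(0.0, chromosome.genomic_length_mb, size=n))


# ---------------------------------------------------------------------------
# population simulation


def simulate_population(
    genotype: GenotypeSpec,
    karyotype: Karyotype,
    n_cells: int,
    params: CoarseningParams,
    rng: np.random.Generator,
    sample_prefix: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate ``n_cells`` meioses; return focus counts and a crossover table.

    For SC-intact genotypes each cell runs one coarsening simulation per
    chromosome; the per-cell MLH1 prediction is the total designated-focus
    count and one transmitted chromatid set is drawn by 50% thinning.  For
    *zyp1* genotypes chromatid CO counts are Poisson/uniform per chromosome
    and the focus-count prediction is an independent bivalent-level Poisson
    draw with twice the chromatid mean.

    Each cell consumes its own child generator spawned from ``rng``, so
    results do not depend on how the execution is batched internally.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    prefix = sample_prefix if sample_prefix is not None else genotype.name
    cell_rngs = rng.spawn(n_cells)
    sample_ids = [f"{prefix}_{i:05d}" for i in range(n_cells)]
    focus_counts = np.zeros(n_cells, dtype=np.int64)
    rows: list[tuple] = []

    if genotype.zyp1:
        means = dict(genotype.poisson_means)
        unknown = set(means) - set(karyotype.names)
        if unknown:
            raise ValueError(f"poisson_means for unknown chromosomes: {sorted(unknown)}")
        for i in range(n_cells):
            r = cell_rngs[i]
            for chrom in karyotype:
                lam = means.get(chrom.name, 0.0)
                focus_counts[i] += r.poisson(2.0 * lam)
                for pos in simulate_zyp1_chromatid(chrom, lam, r):
                    rows.append((sample_ids[i], chrom.name, float(pos)))
    else:
        p = params.replace(dosage_factor=genotype.dosage_factor)
        # phase A: per-chromosome batched coarsening (cells share a kernel call)
        designated: dict[str, list[np.ndarray]] = {}
        for chrom in karyotype:
            positions, amounts = simulate_ensemble(
                chrom.sc_length_um, n_cells, p, cell_rngs
            )
            per_cell = []
            for i in range(n_cells):
                keep = amounts[i] > p.m_thresh
                per_cell.append(np.sort(positions[i][keep]))
            designated[chrom.name] = per_cell
        # phase B: thinning + linear genome mapping, in fixed (cell, chromosome) order
        for i in range(n_cells):
            r = cell_rngs[i]
            for chrom in karyotype:
                cos_um = designated[chrom.name][i]
                focus_counts[i] += cos_um.size
                kept = bivalent_to_chromatid(cos_um, r)
                for pos in map_sc_to_genome(
                    kept, chrom.sc_length_um, chrom.genomic_length_mb
                ):
                    rows.append((sample_ids[i], chrom.name, float(pos)))

    table = make_crossover_table(rows) if rows else pd.DataFrame(columns=CROSSOVER_COLUMNS)
    return focus_counts, table
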