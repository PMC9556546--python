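"""Synthetic BC1 sequencing data: marker maps, genotype matrices with
planted crossovers, and window depth profiles with optional trisomy.

The generator emulates the marker-count level of a backcross
genotyping-by-sequencing experiment: biallelic Col/Ler SNP markers, shallow
Poisson read counts per marker, and per-100 kb window depths.  Gamete
genotypes are Col-homozygous vs Col/Ler-heterozygous blocks (backcross to
Col; Ler-homozygous states cannot occur), delimited by the planted
crossover breakpoints.  Planted truth tables are returned alongside, so the
caller and the downstream statistics can be validated end to end without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meiosis import (
    CROSSOVER_COLUMNS,
    GenotypeSpec,
    Karyotype,
    make_crossover_table,
)

__all__ = [
    "TrisomySpec",
    "SyntheticPopulationSpec",
    "generate_marker_map",
    "generate_population_markers",
    "generate_depth_profile",
]


@dataclass(frozen=True)
class TrisomySpec:
    """Planted trisomy: ``fraction`` of samples carry a third copy of
    ``chromosome``.  With ``het_centromere`` the extra copy makes the
    centromeric region heterozygous (two Col + one Ler chromatid around the
    centromere), the depth signature of meiosis-I missegregation."""

    fraction: float
    chromosome: str
    het_centromere: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Study conditions for one synthetic BC1 population.

    ``marker_density_per_kb`` defaults to one marker per 5 kb and
    ``mean_depth`` (mean reads per marker) to 2, giving ~20 reads per 50 kb
    calling window — a deliberately scaled-down stand-in for the real
    situation of very dense hybrid SNPs at shallow depth, where windows
    collect on the order of a hundred reads.  ``masks`` lists
    recombination-suppressed intervals (bp) per chromosome, e.g.
    pericentromeres, which receive no planted breakpoints.
    """

    n_samples: int
    karyotype: Karyotype
    marker_density_per_kb: float = 0.2
    mean_depth: float = 2.0
    genotyping_error: float = 0.0
    masks: Mapping[str, Sequence[tuple[int, int]]] | None = None
    trisomy: TrisomySpec | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.genotyping_error < 1:
            raise ValueError("error rate must be in [0, 1)")
        if self.masks:
            for chrom, ivals in self.masks.items():
                limit = self.karyotype[chrom].genomic_length_mb * 1e6
                for a, b in ivals:
                    if not 0 <= a < b <= limit:
                        raise ValueError(f"mask {a}-{b} outside chromosome {chrom}")


def generate_marker_map(
    karyotype: Karyotype, density_per_kb: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Uniformly placed biallelic marker positions (bp) per chromosome."""
    if density_per_kb <= 0:
        raise ValueError("density must be positive")
    out = {}
    for chrom in karyotype:
        length = int(round(chrom.genomic_length_mb * 1e6))
        n = int(round(density_per_kb * length / 1000))
        pos = np.unique(rng.integers(1, length + 1, size=n))
        out[chrom.name] = pos
    return out


def _in_mask(pos_bp: float, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(a <= pos_bp < b for a, b in intervals)


def _chromatid_breakpoints(
    spec: SyntheticPopulationSpec,
    co_source,
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, str], np.ndarray], pd.DataFrame]:
    """Planted breakpoints (bp) per (sample, chromosome) plus truth table."""
    samples = [f"synt_{i:05d}" for i in range(spec.n_samples)]
    masks = spec.masks or {}
    bps: dict[tuple[str, str], np.ndarray] = {}
    truth_rows = []
    if isinstance(co_source, pd.DataFrame):
        limit_bp = {
            c.name: int(round(c.genomic_length_mb * 1e6)) for c in spec.karyotype
        }
        for r in co_source.itertuples():
            bp = int(round(r.position_mb * 1e6))
            if not 0 <= bp <= limit_bp[str(r.chromosome)]:
                raise ValueError(
                    f"CO at {r.position_mb} Mb outside chromosome {r.chromosome}"
                )
        # samples beyond those present in co_source carry no crossovers
        # (a crossover table has no rows for CO-free samples)
        source_samples = list(pd.unique(co_source["sample"]))[: spec.n_samples]
        for k, new in enumerate(samples):
            old = source_samples[k] if k < len(source_samples) else None
            sub = (
                co_source[co_source["sample"] == old]
                if old is not None
                else co_source.iloc[0:0]
            )
            for chrom in spec.karyotype:
                pos = np.sort(
                    sub.loc[sub["chromosome"] == chrom.name, "position_mb"].to_numpy()
                )
                bp = np.round(pos * 1e6).astype(np.int64)
                bps[(new, chrom.name)] = bp
                truth_rows.extend((new, chrom.name, p) for p in pos)
    elif isinstance(co_source, GenotypeSpec) and co_source.zyp1:
        means = dict(co_source.poisson_means)
        for sample in samples:
            for chrom in spec.karyotype:
                lam = means.get(chrom.name, 0.0)
                n = rng.poisson(lam)
                length = chrom.genomic_length_mb * 1e6
                pos = []
                for _ in range(n):
                    p = rng.uniform(0, length)
                    while chrom.name in masks and _in_mask(p, masks[chrom.name]):
                        p = rng.uniform(0, length)
                    pos.append(p)
                bp = np.sort(np.asarray(pos, dtype=np.int64)) if pos else np.empty(0, np.int64)
                bps[(sample, chrom.name)] = bp
                truth_rows.extend((sample, chrom.name, p / 1e6) for p in bp)
    else:
        raise TypeError("co_source must be a crossover table or a zyp1 GenotypeSpec")
    truth = (
        make_crossover_table([(s, c, p, np.nan, np.nan, "truth") for s, c, p in truth_rows])
        if truth_rows
        else pd.DataFrame(columns=CROSSOVER_COLUMNS)
    )
    return bps, truth


def generate_population_markers(
    spec: SyntheticPopulationSpec,
    co_source,
    rng: np.random.Generator,
    marker_map: Mapping[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker genotype matrix with planted crossovers, plus the truth table.

    ``co_source`` is either a crossover table whose first ``n_samples``
    samples provide the planted breakpoints (e.g. output of
    :func:`meiocross.meiosis.simulate_population`), or a *zyp1*
    :class:`GenotypeSpec`, in which case Poisson/uniform breakpoints are
    drawn internally, honouring the recombination masks.

    Read counts are Poisson(``mean_depth``) per marker with a binomial
    Col/Ler split given the local genotype; ``genotyping_error`` flips each
    read's allele independently.  Returns ``(markers, truth)``.
    """
    if marker_map is None:
        marker_map = generate_marker_map(spec.karyotype, spec.marker_density_per_kb, rng)
    bps, truth = _chromatid_breakpoints(spec, co_source, rng)
    samples = sorted({s for s, _ in bps})
    tri = spec.trisomy
    n_tri = int(round(tri.fraction * spec.n_samples)) if tri else 0
    trisomic = set(rng.choice(samples, size=n_tri, replace=False)) if n_tri else set()
    err = spec.genotyping_error

    frames = []
    for sample in samples:
        for chrom in spec.karyotype:
            pos = marker_map[chrom.name]
            breaks = bps[(sample, chrom.name)]
            # phase 0/1 of the F1 chromatid at the chromosome start
            phase0 = int(rng.integers(0, 2))
            segment = phase0 + np.searchsorted(breaks, pos, side="right")
            is_het = (segment % 2) == 1  # odd segments carry the Ler haplotype
            depth = spec.mean_depth
            p_col = np.where(is_het, 0.5, 1.0)
            if tri and sample in trisomic and chrom.name == tri.chromosome:
                depth *= 1.5
                if tri.het_centromere:
                    # third copy = extra Col chromatid; het markers see 2/3 Col
                    p_col = np.where(is_het, 2.0 / 3.0, 1.0)
            p_col = p_col * (1 - err) + (1 - p_col) * err
            n_reads = rng.poisson(depth, size=pos.size)
            col = rng.binomial(n_reads, p_col)
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "chromosome": chrom.name,
                        "position_bp": pos,
                        "col_reads": col,
                        "ler_reads": n_reads - col,
                    }
                )
            )
    markers = pd.concat(frames, ignore_index=True)
    return markers, truth


def generate_depth_profile(
    spec: SyntheticPopulationSpec,
    rng: np.random.Generator,
    window_bp: int = 100_000,
    reads_per_x: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window sequencing depth with Poisson noise and planted trisomy.

    Depth of each non-overlapping ``window_bp`` window is
    Poisson(mean_depth * reads_per_x) / reads_per_x, scaled 1.5x on the
    trisomic chromosome of trisomic samples.  Returns ``(depths, truth)``
    where truth lists each sample's trisomic chromosome ("" if euploid).
    """
    samples = [f"synt_{i:05d}" for i in range(spec.n_samples)]
    tri = spec.trisomy
    n_tri = int(round(tri.fraction * spec.n_samples)) if tri else 0
    trisomic = set(rng.choice(samples, size=n_tri, replace=False)) if n_tri else set()
    rows = []
    truth_rows = []
    for sample in samples:
        truth_rows.append((sample, tri.chromosome if sample in trisomic else ""))
        for chrom in spec.karyotype:
            length = int(round(chrom.genomic_length_mb * 1e6))
            starts = np.arange(0, length, window_bp, dtype=np.int64)
            ends = np.minimum(starts + window_bp, length)
            scale = 1.5 if (tri and sample in trisomic and chrom.name == tri.chromosome) else 1.0
            lam = spec.mean_depth * reads_per_x * scale * (ends - starts) / window_bp
            depth = rng.poisson(lam) / reads_per_x * (window_bp / np.maximum(ends - starts, 1))
            for s, e, d in zip(starts, ends, depth):
                rows.append((sample, chrom.name, int(s), int(e), float(d)))
    depths = pd.DataFrame(rows, columns=["sample", "chromosome", "start_bp", "end_bp", "depth"])
    truth = pd.DataFrame(truth_rows, columns=["sample", "trisomic_chromosome"])
    return depths, truth
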