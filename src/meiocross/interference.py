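"""Crossover interference and distribution statistics.

All functions consume crossover tables (see :mod:`meiocross.meiosis`) in
which one row is one crossover of one sample (a transmitted chromatid set).
Samples without any crossover on a chromosome carry information too — they
enter the coefficient-of-coincidence denominators — so functions that need
population frequencies accept an explicit ``n_samples``; by default the
number of distinct sample ids in the table is used.

Implemented statistics:

* inter-CO distance distribution for chromosomes with exactly two COs,
  and its no-interference permutation null (all cross-sample position
  pairs, downsampled per chromosome to the observed chromosome shares);
* two-sided Mann-Whitney comparison of observed vs null distances;
* coefficient of coincidence (CoC) curves on 13 equal intervals: for an
  interval pair, CoC = f(CO in both) / (f(CO in i) * f(CO in j)), with
  presence meaning >= 1 CO.  CoC ~ 1 means independent placement, < 1
  interference;
* crossover-count summaries (per-chromosome means, correlation with
  chromosome size, between-chromosome covariation);
* sliding-window CO density profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meiosis import Karyotype

__all__ = [
    "DistanceNull",
    "CoCCurve",
    "COCountSummary",
    "two_co_distances",
    "permutation_null",
    "compare_distance_distributions",
    "coc_curve",
    "co_count_summaries",
    "co_density_profile",
]


@dataclass
class DistanceNull:
    """No-interference inter-CO distance set, per chromosome."""

    distances: dict[str, np.ndarray]
    downsampled_to: dict[str, int]

    def pooled(self) -> np.ndarray:
        if not self.distances:
            return np.empty(0)
        return np.concatenate(list(self.distances.values()))

    def __len__(self) -> int:
        return sum(v.size for v in self.distances.values())


@dataclass
class CoCCurve:
    """Coefficient-of-coincidence values for every defined interval pair.

    ``pairs`` has one row per (chromosome, interval i < interval j) with the
    midpoint-to-midpoint distance (Mb) and the CoC value; ``curve`` bins the
    pairs by distance (bin width = one interval width per chromosome) and
    averages.
    """

    n_intervals: int
    pairs: pd.DataFrame
    curve: pd.DataFrame

    @property
    def mean_coc(self) -> float:
        """Mean CoC over all defined interval pairs."""
        return float(self.pairs["coc"].mean())

    def mean_adjacent(self) -> float:
        """Mean CoC over adjacent interval pairs (|i - j| == 1)."""
        adj = self.pairs[self.pairs["interval_j"] - self.pairs["interval_i"] == 1]
        return float(adj["coc"].mean())


@dataclass
class COCountSummary:
    per_chromosome_mean: pd.Series
    length_correlation: float
    length_correlation_reliable: bool
    between_chromosome_correlation: pd.DataFrame
    per_sample_total: pd.Series


def _two_co_groups(table: pd.DataFrame):
    """(sample, chromosome) groups carrying exactly two COs."""
    counts = table.groupby(["sample", "chromosome"], sort=False).size()
    return counts[counts == 2].index


def two_co_distances(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """|pos2 - pos1| per chromosome over samples with exactly two COs there."""
    out: dict[str, list[float]] = {}
    eligible = set(_two_co_groups(table))
    for (sample, chrom), sub in table.groupby(["sample", "chromosome"], sort=False):
        if (sample, chrom) in eligible:
            pos = np.sort(sub["position_mb"].to_numpy())
            out.setdefault(str(chrom), []).append(float(pos[1] - pos[0]))
    return {c: np.array(v) for c, v in sorted(out.items())}


def permutation_null(
    table: pd.DataFrame,
    rng: np.random.Generator,
    target_total: int | None = None,
    exact_limit: int = 3000,
) -> DistanceNull:
    """No-interference distance null from cross-sample CO position pairs.

    For each chromosome, the CO positions of every sample with exactly two
    COs are pooled and the distances of all position pairs (within- and
    cross-sample) form the null.  The per-chromosome null is then
    downsampled so each chromosome contributes the same share as in the
    observed two-CO data.  When a pool exceeds ``exact_limit`` positions the
    pair set is sampled randomly instead of enumerated, which is equivalent
    after downsampling.

    Raises ValueError when no chromosome has an eligible sample.
    """
    eligible = _two_co_groups(table)
    if len(eligible) == 0:
        raise ValueError("no (sample, chromosome) group with exactly two COs")
    eligible_set = set(eligible)
    pools: dict[str, list[float]] = {}
    n_obs: dict[str, int] = {}
    for (sample, chrom), sub in table.groupby(["sample", "chromosome"], sort=False):
        if (sample, chrom) in eligible_set:
            pools.setdefault(str(chrom), []).extend(sub["position_mb"].tolist())
            n_obs[str(chrom)] = n_obs.get(str(chrom), 0) + 1
    total_obs = sum(n_obs.values())
    shares = {c: n / total_obs for c, n in n_obs.items()}
    n_pairs = {c: len(p) * (len(p) - 1) // 2 for c, p in pools.items()}
    if target_total is None:
        # largest total for which every chromosome can supply its share
        target_total = min(
            min(int(n_pairs[c] / shares[c]) for c in pools), 100_000
        )
    distances: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for chrom in sorted(pools):
        pos = np.asarray(pools[chrom])
        k = min(int(round(target_total * shares[chrom])), n_pairs[chrom])
        k = max(k, 1)
        if pos.size <= exact_limit:
            d = np.abs(pos[:, None] - pos[None, :])[np.triu_indices(pos.size, k=1)]
            if k < d.size:
                d = rng.choice(d, size=k, replace=False)
        else:
            i = rng.integers(0, pos.size, size=k)
            j = rng.integers(0, pos.size - 1, size=k)
            j[j >= i] += 1  # exclude self-pairs
            d = np.abs(pos[i] - pos[j])
        distances[chrom] = d
        sizes[chrom] = int(d.size)
    return DistanceNull(distances, sizes)


def compare_distance_distributions(observed, null) -> float:
    """Two-sided Mann-Whitney p-value between observed and null distances.

    ``null`` may be a :class:`DistanceNull` (pooled) or an array.  Uses the
    exact distribution when both sides have <= 8 values and no ties, the
    tie-corrected normal approximation otherwise.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    nul = null.pooled() if isinstance(null, DistanceNull) else np.asarray(null, dtype=float).ravel()
    if obs.size == 0 or nul.size == 0:
        raise ValueError("both distance sets must be non-empty")
    ties = np.unique(np.concatenate([obs, nul])).size < obs.size + nul.size
    method = "exact" if (obs.size <= 8 and nul.size <= 8 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(obs, nul, alternative="two-sided", method=method).pvalue)


def coc_curve(
    table: pd.DataFrame,
    karyotype: Karyotype,
    n_intervals: int = 13,
    exclude: tuple[str, ...] = (),
    n_samples: int | None = None,
) -> CoCCurve:
    """Coefficient-of-coincidence curve on equal-Mb intervals.

    Every chromosome in ``karyotype`` (minus ``exclude``) is divided into
    ``n_intervals`` equal intervals.  For each interval pair (i < j),
    CoC = f(i and j) / (f(i) * f(j)) over samples, where f uses >= 1-CO
    presence per interval; pairs with zero expected co-occurrence are
    omitted.  ``n_samples`` is the population size (defaults to the number
    of distinct sample ids in the table); samples absent from a chromosome
    count as zero-presence everywhere there.
    """
    if n_intervals < 2:
        raise ValueError("need at least two intervals")
    work = table[~table["chromosome"].isin(exclude)]
    if work.empty:
        raise ValueError("crossover table empty after exclusions")
    sample_index = pd.Index(sorted(table["sample"].unique()))
    if n_samples is None:
        n_samples = len(sample_index)
    elif n_samples < len(sample_index):
        raise ValueError("n_samples smaller than the number of samples in the table")
    pair_rows = []
    for chrom in karyotype:
        if chrom.name in exclude:
            continue
        sub = work[work["chromosome"] == chrom.name]
        width = chrom.genomic_length_mb / n_intervals
        presence = np.zeros((n_samples, n_intervals), dtype=bool)
        if not sub.empty:
            iv = np.minimum(
                (sub["position_mb"].to_numpy() / width).astype(int), n_intervals - 1
            )
            si = sample_index.get_indexer(sub["sample"])
            presence[si, iv] = True
        f = presence.mean(axis=0)
        mids = (np.arange(n_intervals) + 0.5) * width
        for i in range(n_intervals):
            for j in range(i + 1, n_intervals):
                expected = f[i] * f[j]
                if expected == 0:
                    continue
                f_both = np.mean(presence[:, i] & presence[:, j])
                pair_rows.append(
                    (chrom.name, i, j, float(mids[j] - mids[i]), float(f_both / expected))
                )
    pairs = pd.DataFrame(
        pair_rows, columns=["chromosome", "interval_i", "interval_j", "distance_mb", "coc"]
    )
    if pairs.empty:
        raise ValueError("all interval pairs undefined (no expected co-occurrence)")
    # distance bins of one interval width: adjacent pairs fall in bin 1, etc.
    steps = pairs["interval_j"] - pairs["interval_i"]
    curve = (
        pairs.assign(separation=steps)
        .groupby("separation")
        .agg(distance_mb=("distance_mb", "mean"), mean_coc=("coc", "mean"), n_pairs=("coc", "size"))
        .reset_index()
    )
    return CoCCurve(n_intervals, pairs, curve)


def co_count_summaries(
    table: pd.DataFrame, karyotype: Karyotype, n_samples: int | None = None
) -> COCountSummary:
    """Per-chromosome mean counts, size correlation and covariation matrix."""
    if table.empty:
        raise ValueError("crossover table is empty")
    samples = sorted(table["sample"].unique())
    counts = (
        table.groupby(["sample", "chromosome"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=samples, fill_value=0)
        .reindex(columns=karyotype.names, fill_value=0)
    )
    if n_samples is not None and n_samples > len(counts):
        # append all-zero rows for samples with no COs anywhere
        extra = pd.DataFrame(
            0, index=[f"_zero_{i}" for i in range(n_samples - len(counts))], columns=counts.columns
        )
        counts = pd.concat([counts, extra])
    means = counts.mean(axis=0)
    lengths = np.array([c.genomic_length_mb for c in karyotype])
    reliable = len(karyotype) >= 3
    if np.std(means.to_numpy()) == 0 or np.std(lengths) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(means.to_numpy(), lengths)[0])
    return COCountSummary(
        per_chromosome_mean=means,
        length_correlation=r,
        length_correlation_reliable=reliable,
        between_chromosome_correlation=counts.corr(),
        per_sample_total=counts.sum(axis=1),
    )


def co_density_profile(
    table: pd.DataFrame,
    karyotype: Karyotype,
    window_mb: float = 1.0,
    step_mb: float = 0.05,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Sliding-window CO density along each chromosome.

    Returns a BED-like frame (chromosome, start_bp, end_bp, density) where
    density is the CO count in the window divided by the number of samples.
    Windows start every ``step_mb`` from 0 while the start lies inside the
    chromosome; the last windows are clipped at the chromosome end.
    """
    if window_mb <= 0:
        raise ValueError("window must be positive")
    if step_mb <= 0:
        raise ValueError("step must be positive")
    if n_samples is None:
        n_samples = max(int(table["sample"].nunique()), 1) if not table.empty else 1
    rows = []
    for chrom in karyotype:
        length = chrom.genomic_length_mb
        sub = table[table["chromosome"] == chrom.name] if not table.empty else table
        pos = np.sort(sub["position_mb"].to_numpy()) if not sub.empty else np.empty(0)
        starts = np.arange(0.0, length, step_mb)
        ends = np.minimum(starts + window_mb, length)
        # half-open [start, end) windows, BED-like
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        dens = (hi - lo) / n_samples
        for s, e, d in zip(starts, ends, dens):
            rows.append((chrom.name, int(round(s * 1e6)), int(round(e * 1e6)), float(d)))
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "density"])
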