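"""Crossover calling from backcross (BC1) marker genotypes, sample QC and
depth-based aneuploidy screening.

A BC1 sample (hybrid backcrossed to the Col parent) is homozygous Col or
heterozygous Col/Ler in blocks along each chromosome; block boundaries are
the crossovers of the transmitted chromatid.  Calling proceeds through
sliding 50 kb windows (25 kb step): the Col allele frequency of each
window classifies it homozygous / heterozygous / ambiguous, runs of
consistently classified windows form blocks, and each block transition
yields one crossover call with an interval spanning the flanking
informative windows and a point position drawn uniformly inside it.

Marker tables are DataFrames with columns ``sample, chromosome,
position_bp, col_reads, ler_reads``; depth tables have ``sample,
chromosome, start_bp, end_bp, depth``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .meiosis import Karyotype

__all__ = [
    "CallerConfig",
    "window_allele_freq",
    "call_crossovers",
    "calls_to_crossover_table",
    "qc_sample",
    "aneuploidy_screen",
]

MARKER_COLUMNS = ["sample", "chromosome", "position_bp", "col_reads", "ler_reads"]
DEPTH_COLUMNS = ["sample", "chromosome", "start_bp", "end_bp", "depth"]


@dataclass(frozen=True)
class CallerConfig:
    """Window-classification thresholds of the sliding-window caller.

    Windows with Col allele frequency >= ``hom_min`` are homozygous Col,
    within [``het_min``, ``het_max``] heterozygous, anything else (or no
    reads) ambiguous.  A genotype block needs ``min_run`` consecutive
    informative windows; ambiguous windows are skipped, not state-breaking.
    """

    window_bp: int = 50_000
    step_bp: int = 25_000
    hom_min: float = 0.95
    het_min: float = 0.25
    het_max: float = 0.75
    min_run: int = 3

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window and step must be positive")
        if not (0 <= self.het_min <= self.het_max <= self.hom_min <= 1):
            raise ValueError("thresholds must satisfy 0<=het_min<=het_max<=hom_min<=1")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def window_allele_freq(
    markers: pd.DataFrame,
    karyotype: Karyotype,
    window_bp: int = 50_000,
    step_bp: int = 25_000,
) -> pd.DataFrame:
    """Col allele frequency in sliding windows, per sample and chromosome.

    Windows without reads are flagged uninformative (``af`` = NaN): marker
    absence is missing data, not evidence of either genotype.
    Returns columns sample, chromosome, start_bp, end_bp, col_reads,
    total_reads, af, informative.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window and step must be positive")
    rows = []
    for (sample, chrom_name), sub in markers.groupby(["sample", "chromosome"], sort=True):
        length = int(round(karyotype[str(chrom_name)].genomic_length_mb * 1e6))
        sub = sub.sort_values("position_bp")
        pos = sub["position_bp"].to_numpy()
        col = np.concatenate([[0], np.cumsum(sub["col_reads"].to_numpy())])
        tot = np.concatenate(
            [[0], np.cumsum((sub["col_reads"] + sub["ler_reads"]).to_numpy())]
        )
        starts = np.arange(0, length, step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        col_w = col[hi] - col[lo]
        tot_w = tot[hi] - tot[lo]
        with np.errstate(invalid="ignore"):
            af = np.where(tot_w > 0, col_w / np.maximum(tot_w, 1), np.nan)
        for s, e, cw, tw, a in zip(starts, ends, col_w, tot_w, af):
            rows.append((sample, chrom_name, int(s), int(e), int(cw), int(tw), a, tw > 0))
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "chromosome",
            "start_bp",
            "end_bp",
            "col_reads",
            "total_reads",
            "af",
            "informative",
        ],
    )


def _classify(af: np.ndarray, cfg: CallerConfig) -> np.ndarray:
    """2 = homozygous Col, 1 = heterozygous, 0 = ambiguous."""
    state = np.zeros(af.size, dtype=np.int8)
    state[af >= cfg.hom_min] = 2
    state[(af >= cfg.het_min) & (af <= cfg.het_max)] = 1
    return state


def call_crossovers(
    window_afs: pd.DataFrame,
    rng: np.random.Generator,
    config: CallerConfig | None = None,
) -> pd.DataFrame:
    """Call crossovers from window allele frequencies.

    Returns one row per call: sample, chromosome, interval_start_bp,
    interval_end_bp (spanning the last informative window of the left block
    through the first of the right block), point_bp (uniform in the
    interval, seeded by ``rng``) and transition ("col_to_het" or
    "het_to_col").  Samples whose windows are all ambiguous produce no
    calls.
    """
    cfg = config or CallerConfig()
    out = []
    for (sample, chrom), sub in window_afs.groupby(["sample", "chromosome"], sort=True):
        sub = sub[sub["informative"]].sort_values("start_bp")
        if sub.empty:
            continue
        starts = sub["start_bp"].to_numpy()
        ends = sub["end_bp"].to_numpy()
        state = _classify(sub["af"].to_numpy(), cfg)
        keep = state > 0
        starts, ends, state = starts[keep], ends[keep], state[keep]
        if state.size == 0:
            continue
        # compress into runs of equal state
        change = np.flatnonzero(np.diff(state)) + 1
        run_bounds = np.concatenate([[0], change, [state.size]])
        blocks = []  # (state, first_window_idx, last_window_idx)
        for a, b in zip(run_bounds[:-1], run_bounds[1:]):
            if b - a >= cfg.min_run:
                blocks.append((state[a], a, b - 1))
        # merge neighbouring blocks left in the same state
        merged = []
        for blk in blocks:
            if merged and merged[-1][0] == blk[0]:
                merged[-1] = (blk[0], merged[-1][1], blk[2])
            else:
                merged.append(blk)
        for left, right in zip(merged[:-1], merged[1:]):
            lo = int(starts[left[2]])
            hi = int(ends[right[1]])
            if hi <= lo:  # overlapping windows; keep a non-empty interval
                lo, hi = min(lo, hi), max(lo, hi) + 1
            point = int(rng.integers(lo, hi))
            transition = "col_to_het" if left[0] == 2 else "het_to_col"
            out.append((sample, chrom, lo, hi, point, transition))
    return pd.DataFrame(
        out,
        columns=[
            "sample",
            "chromosome",
            "interval_start_bp",
            "interval_end_bp",
            "point_bp",
            "transition",
        ],
    )


def calls_to_crossover_table(calls: pd.DataFrame) -> pd.DataFrame:
    """View crossover calls as a crossover table for the statistics stages."""
    from .meiosis import make_crossover_table

    rows = [
        (
            r.sample,
            r.chromosome,
            r.point_bp / 1e6,
            r.interval_start_bp,
            r.interval_end_bp,
            "chromatid",
        )
        for r in calls.itertuples()
    ]
    return make_crossover_table(rows)


def qc_sample(
    sample_windows: pd.DataFrame,
    mean_depth: float,
    min_depth: float = 0.1,
    contamination_band: tuple[float, float] = (0.8, 0.9),
    max_contaminated_fraction: float = 0.05,
) -> tuple[bool, str]:
    """Sample QC: coverage and contamination filters.

    Fails with reason ``low_coverage`` when ``mean_depth`` < 0.1x, or
    ``contamination`` when more than 5% of the informative windows have a
    Col allele frequency in [0.8, 0.9] — the signature of reads from a
    second, unrelated individual diluting homozygous windows.
    Returns (passed, reason); reason is "" on pass.
    """
    if mean_depth < min_depth:
        return False, "low_coverage"
    informative = sample_windows[sample_windows["informative"]]
    if len(informative):
        af = informative["af"]
        lo, hi = contamination_band
        frac = float(((af >= lo) & (af <= hi)).mean())
        if frac > max_contaminated_fraction:
            return False, "contamination"
    return True, ""


def aneuploidy_screen(
    depths: pd.DataFrame,
    fold_change_min: float = 1.2,
    p_max: float = 1e-20,
    min_windows: int = 20,
) -> pd.DataFrame:
    """Screen samples for aneuploid chromosomes from 100 kb window depths.

    Per sample, every chromosome pair is compared with a two-sided
    Mann-Whitney test on window depths; p-values are Benjamini-Hochberg
    adjusted across the pairs of that sample.  A chromosome is flagged when,
    against a majority of the other chromosomes, it shows a median depth
    fold change above ``fold_change_min`` (gain; below its reciprocal for a
    loss) together with adjusted p < ``p_max``.

    Returns one row per (sample, chromosome) with columns sample,
    chromosome, direction ("gain"/"loss"/""), median_fold_change,
    n_sig_pairs, min_adj_p, flagged, reliable.
    """
    out = []
    for sample, sub in depths.groupby("sample", sort=True):
        chroms = sorted(sub["chromosome"].unique())
        depth_by_chrom = {
            c: sub.loc[sub["chromosome"] == c, "depth"].to_numpy() for c in chroms
        }
        reliable = len(chroms) >= 2 and all(
            v.size >= min_windows for v in depth_by_chrom.values()
        )
        pairs = [(a, b) for i, a in enumerate(chroms) for b in chroms[i + 1 :]]
        pvals, fcs = [], []
        for a, b in pairs:
            da, db = depth_by_chrom[a], depth_by_chrom[b]
            p = stats.mannwhitneyu(da, db, alternative="two-sided").pvalue
            med_b = np.median(db)
            fc = np.median(da) / med_b if med_b > 0 else np.inf
            pvals.append(p)
            fcs.append(fc)
        adj = multipletests(pvals, method="fdr_bh")[1] if pairs else np.empty(0)
        for c in chroms:
            gain = loss = 0
            med_fcs, min_p = [], 1.0
            for (a, b), fc, q in zip(pairs, fcs, adj):
                if c == a:
                    rel = fc
                elif c == b:
                    rel = 1.0 / fc if fc > 0 else np.inf
                else:
                    continue
                med_fcs.append(rel)
                min_p = min(min_p, q)
                if q < p_max:
                    if rel > fold_change_min:
                        gain += 1
                    elif rel < 1.0 / fold_change_min:
                        loss += 1
            n_other = len(chroms) - 1
            direction = ""
            if reliable and n_other > 0:
                if gain > n_other / 2:
                    direction = "gain"
                elif loss > n_other / 2:
                    direction = "loss"
            out.append(
                (
                    sample,
                    c,
                    direction,
                    float(np.median(med_fcs)) if med_fcs else np.nan,
                    max(gain, loss),
                    float(min_p),
                    direction != "",
                    reliable,
                )
            )
    return pd.DataFrame(
        out,
        columns=[
            "sample",
            "chromosome",
            "direction",
            "median_fold_change",
            "n_sig_pairs",
            "min_adj_p",
            "flagged",
            "reliable",
        ],
    )
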