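# Methods

## The coarsening model of crossover patterning

Class I meiotic crossovers (COs) in Arabidopsis are marked by large HEI10
foci that emerge from many small ones during pachytene.  `meiocross` models
this as diffusion-mediated coarsening along the synaptonemal complex (SC):
HEI10 at concentration `c(x, t)` diffuses along an SC of length `L` (µm)
and is exchanged with `N` point foci of amounts `M_i` at positions `x_i`:

    dM_i/dt = Λ [ c(x_i) − c_eq(M_i) ],
    ∂c/∂t   = D ∂²c/∂x² − Λ Σ_i δ(x − x_i) [ c(x_i) − c_eq(M_i) ],

with no-flux ends and the size-dependent equilibrium concentration

    c_eq(M) = c0_eq · M / (1 + M^(1+α)).

On the decreasing branch of `c_eq` (large M) a bigger focus pins the local
concentration lower than a smaller one, so material flows through the SC
pool from small foci to large — Ostwald-ripening-like competition that
leaves a few large, well-spaced winners.  Foci with final `M > M_thresh`
are "designated": they are taken to recruit MLH1 and mature into class I
COs.  Interference emerges mechanistically: a large focus suppresses the
growth of neighbours over the length scale HEI10 explores during the run,
without any dedicated inhibitory signal.

### Parameters

| symbol | name | default | units |
|---|---|---|---|
| D | `diffusivity` | 1.1 | µm²/s |
| Λ | `exchange_rate` | 2.1 | µm/s |
| α | `alpha` | 0.25 | – |
| c0_eq | `c0_eq` | 1.35 | a.u./µm |
| y | `dosage_factor` | genotype-dependent | – |
| M_init | `y · m_init_base` | y·3.4 | a.u. |
| σ_init | `y · sigma_init_base` | y·1.1 | a.u. |
| c_init | `y · c_init_base` | y·1.4 | a.u./µm |
| – | `focus_density` | 4 | foci/µm |
| T | `duration` | 36 000 (10 h) | s |
| – | `n_grid` | 50 | nodes |
| M_thresh | `m_thresh` | 3 | a.u. |

The dosage factor `y` summarizes HEI10 expression: it scales the initial
SC concentration and the initial focus-size distribution together.  Preset
values are 2 (wild-type Col), 6/8 (heterozygous/homozygous HEI10
overexpression, Col), 1.5 (wild-type Col/Ler hybrid) and 5.5 (heterozygous
overexpression in the hybrid).  The 10 h duration corresponds to pachytene;
the model is run to this time rather than to completion, which is what
leaves more than one focus per SC.

### Initial conditions

Concentration uniform at `y·1.4` a.u./µm; `N = round(4L)` foci placed
i.i.d. uniformly on `[0, L]` (an equally-spaced option exists behind a
flag) with amounts drawn by rejection from a normal with mean `y·3.4` and
s.d. `y·1.1`, truncated at ±3 s.d.  All randomness flows from one seeded
`numpy` generator per simulation.

### Numerics

* Grid: `n_grid` nodes spanning `[0, L]` inclusive, `Δx = L/(n_grid−1)`;
  each focus exchanges with its nearest node, several foci may share one.
* The δ-sinks are node-local terms of magnitude `Λ/Δx`, so each focus's
  gain equals its host cell's loss exactly and the total
  `Δx·Σc_j + ΣM_i` is conserved to rounding (measured drift over a full
  10 h run: ~1e−13 relative, versus the 1e−8 requirement).
* No-flux boundaries use the finite-volume ghost form (`c[−1] = c[0]`),
  the variant of the reflecting boundary that conserves the uniform-weight
  total above exactly.  (Reflecting about the boundary *node* instead,
  `c[−1] = c[1]`, leaks ~1% of the mass over 10 h and is not used.)
* Explicit Euler time stepping with
  `dt = dt_safety · min(Δx²/(2D), 2Δx/(Λ·k_max))`, where `k_max` is the
  maximum number of foci sharing a node — both terms are the linear
  stability limits of their operators.  The default `dt_safety = 0.05`
  keeps the dt-discretization error of final focus amounts below 1e−3
  (measured by dt-halving across seeds, worst case 7e−4).  Large
  Monte-Carlo batches use `dt_safety = 0.25`: still stable, ~0.3% error on
  the largest focus amounts, and designation counts identical to the
  accurate profile in paired runs — negligible against Monte-Carlo noise.
* If an Euler step would drive `M_i < 0` the flux is limited so the focus
  lands exactly on zero; zero-mass foci stay in the system and may regrow
  (at `M = 0` the equilibrium concentration is zero, so any positive local
  concentration feeds them).  Whether the original implementation removed
  or clamped such foci is not documented; clamping preserves conservation
  and keeps the focus list static.
* Whether "50 grid points" means nodes or cells is equally undocumented;
  we use 50 nodes.  The 50-node grid is part of the model definition
  rather than a converged continuum limit: refining to 100 nodes leaves
  the ensemble mean designated-focus count unchanged (1.70 vs 1.70 over 40
  wild-type seeds, L = 24 µm) but flips the outcome of individual
  marginal seeds (~15%), because near-threshold coarsening races are
  sensitive to how foci share grid nodes.  All downstream statistics are
  ensemble quantities and are insensitive to this.
* Foci are processed in `(node, amount)` order inside the kernel, which
  makes the scheme exactly mirror-symmetric: reflecting all positions
  about `L/2` produces the bitwise-mirrored final state.

## From bivalents to gametes

Each chromosome's bivalent is one independent SC (no HEI10 exchange
between bivalents).  The per-cell MLH1 prediction is the designated-focus
total over the karyotype.  A transmitted chromatid keeps each bivalent CO
independently with probability 1/2, and positions map linearly from SC µm
to genomic Mb.  Karyotypes pair an SC length with a genomic length per
chromosome; the shipped example karyotype uses SC lengths
{24, 21, 19, 17, 15} µm assigned to chromosomes in genomic-size order and
TAIR10 chromosome sizes — SC lengths are cytological inputs the user
should replace with measurements for their material.  Male meiocytes are
modelled by scaling all SC lengths 1.6-fold, the measured male:female
ratio; this is the model's entire account of heterochiasmy.

## The zyp1 (SC-less) null model

Without the SC transverse filament there is no per-chromosome coarsening
substrate, CO positions lose all spatial coupling, and interference and
the SC-length dependence disappear.  Per chromatid and chromosome the CO
count is Poisson with a configurable mean and positions are i.i.d.
uniform.  Per-chromosome means default to a configured total apportioned
proportionally to genomic length (chromosome size tracks CO count in the
data); presets: totals 7.0/7.1 per female/male chromatid set for *zyp1*
(wild-type hybrid means 19.6/6.4 = 3.06 and 14.7/3.1 = 4.74 times the
reported fold changes 2.3 and 1.5), and 19.6/14.7 for *zyp1* with HEI10
overexpression (measured directly).  The focus-count prediction per cell
is a bivalent-level Poisson draw at twice the chromatid mean, since the
chromatid-level model is the defined one.

## Interference statistics

* **Two-CO distances** — for every (sample, chromosome) with exactly two
  COs, the inter-CO distance.  The no-interference reference is a
  permutation null: per chromosome, all pairwise distances among the
  pooled CO positions of those samples (cross-sample and within-sample
  pairs alike), downsampled so each chromosome's share matches its share
  of the observed two-CO data.  Pools beyond 3000 positions switch from
  full enumeration to random pair sampling, which is distributionally
  identical after downsampling.  Observed and null sets are compared with
  a two-sided Mann–Whitney test (`scipy`, exact when both n ≤ 8 without
  ties, tie-corrected normal approximation otherwise).
* **Coefficient of coincidence** — each chromosome is cut into 13
  equal-Mb intervals; for an interval pair, CoC is the observed frequency
  of samples with ≥1 CO in both divided by the product of the single-
  interval presence frequencies.  The population size matters (CO-free
  chromatids belong in the denominators), so the caller can pass
  `n_samples` explicitly.  Pairs are reported per chromosome with their
  midpoint distances, and aggregated by interval separation (one interval
  width per bin).  Chromosome 4 is excluded from interference analyses by
  default in the CLI (transgene translocation and inversion make it
  unusable in the motivating data).
* **Count summaries** — per-chromosome means, Pearson correlation of mean
  count with chromosome size, the between-chromosome count correlation
  matrix (covariation), per-sample totals.
* **Density profiles** — CO point counts in 1 Mb windows every 50 kb,
  normalized per sample, emitted as BED-like half-open intervals.

## Crossover calling and screening

Windows of 50 kb every 25 kb collect Col/Ler read counts; the Col allele
frequency classifies each window (hom-Col at ≥ 0.95, het in [0.25, 0.75],
else ambiguous; no reads = uninformative, never "Ler").  Runs of at least
3 consecutively classified informative windows form blocks; each Col↔Het
block transition is one crossover, its interval spanning the flanking
windows, its point position uniform in the interval (seeded).  The
classification thresholds and run length are declared defaults in
`CallerConfig`, not inferences — the upstream study delegates them to its
caller's reference.  Sample QC fails below 0.1× mean depth or when > 5% of
informative windows sit at allele frequency 0.8–0.9 (contamination).

Aneuploidy screening compares 100 kb window depths between chromosome
pairs (Mann–Whitney, Benjamini–Hochberg across pairs within a sample) and
flags a chromosome showing fold change > 1.2 with adjusted p < 1e−20
against the majority of others, with gain/loss direction.  The p-threshold
is applied to the *adjusted* value (the stricter of the two readings of
the rule).

## Synthetic data

The generators start at marker-count level (alignment and variant
discovery are out of scope).  BC1 genotypes are blocks of hom-Col /
het-Col-Ler delimited by planted breakpoints, with a random phase per
chromosome; reads per marker are Poisson(depth) with a binomial allele
split and per-read allele flips at the genotyping error rate.  Defaults —
0.2 markers/kb, 2 reads/marker, i.e. ~20 reads per calling window — are a
scaled-down stand-in for the real regime of very dense hybrid SNPs at
shallow coverage (hundreds of reads per window); the scaling preserves
window-level classification behaviour while keeping tables small.
Trisomic samples carry two Col copies plus the recombinant chromatid:
1.5× depth on the trisomic chromosome and 2/3 Col allele frequency in
heterozygous regions.  What the generator does *not* emulate: real marker
clustering, structural-variant deserts, mapping bias, batch effects in
depth.  Passing recovery tests therefore validates the window/blocking
logic and thresholds, not robustness to alignment artefacts.

## Problem sizes

Full-scale coarsening runs cost ~1 s per bivalent, so the shipped
validation uses deliberately scaled-down but statistically sufficient
batches, e.g. 60 cells per karyotype for the SC-length ratio (ratio
standard error ~3%, against a ±10% band) and 200–350 bivalents with
three or four independently thinned chromatids each for wild-type CoC
curves (the adjacent-pair CoC sits near zero, far from the
no-interference value of 1).
These sizes are the package's own trade-off and are easily raised via the
API or CLI.

## Known limitations

* No class II (non-interfering) CO pathway: genetic CO counts in contexts
  where class II matters will exceed the model's class I prediction.
* No obligate-CO checkpoint, no focus-size cap — the fixed 10 h stopping
  time is the sole mechanism limiting coarsening.
* The µm→Mb map is linear; real recombination deserts (pericentromeres,
  inversions) enter only through the synthetic generator's masks.
* The zyp1 model reproduces means by construction; it has no mechanistic
  content beyond independence.
* 1-D SC geometry, deterministic exchange dynamics (no Gillespie noise),
  explicit Euler only.
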