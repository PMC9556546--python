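# meiocross

Simulation and analysis of meiotic crossover (CO) patterning in
Arabidopsis-like genomes, for researchers studying recombination control:
how the synaptonemal complex (SC) and the dosage of the pro-crossover E3
ligase HEI10 jointly set crossover number, spacing (interference) and the
male–female difference (heterochiasmy).

## What it implements

**The coarsening model.**  HEI10 diffuses along each SC (length `L`, µm)
and is exchanged with `N` point foci:

    dM_i/dt = Λ [ c(x_i) − c_eq(M_i) ]
    ∂c/∂t   = D ∂²c/∂x² − Λ Σ_i δ(x − x_i) [ c(x_i) − c_eq(M_i) ]
    c_eq(M) = c0_eq · M / (1 + M^(1+α))

with no-flux ends.  Because `c_eq` falls with focus size at large `M`,
large foci out-compete near neighbours (Ostwald-ripening-like coarsening);
after 10 h the few foci above `M_thresh = 3` a.u. are the predicted class I
CO sites.  HEI10 dosage enters as a factor `y` on the initial loading;
SC length sets the total pool per chromosome.  The model yields CO
interference, the SC-length–CO-count relation, and heterochiasmy from the
1.6× longer male SCs, with nothing fit downstream.

**The SC-less (*zyp1*) null.**  Without the SC, CO positions decouple:
Poisson counts per chromatid and uniform positions — flat coefficient of
coincidence at 1, no SC-length dependence.

**The analysis pipeline** of a backcross (BC1) sequencing study:
sliding-window CO calling from Col/Ler marker read counts (50 kb / 25 kb
windows), sample QC (coverage, contamination), inter-CO distance
distributions with a cross-sample permutation null and Mann–Whitney
comparison, coefficient-of-coincidence curves on 13 intervals, CO density
profiles, count summaries, and depth-based trisomy screening
(Mann–Whitney + FDR, fold change > 1.2 and p < 1e−20).  Synthetic
generators produce marker matrices with planted COs and depth profiles
with planted trisomies, so everything is testable without external data.

See `docs/methods.md` for model details, parameter tables and numerical
choices.

## Worked example

Simulate wild-type hybrid female meiosis (coarsening model, dosage
y = 1.5, example karyotype), then a *zyp1* HEI10-overexpressor null
population, and compare:

```bash
meiocross simulate --genotype wt_hybrid --sex female --n-cells 20 \
    --dt-safety 0.25 --seed 1 --out-dir out/wt
meiocross zyp1-null --genotype zyp1_hei10oe_hybrid --n-cells 2000 \
    --seed 1 --out-dir out/zyp1oe
meiocross stats --crossovers out/zyp1oe/crossovers.tsv --seed 1 \
    --n-samples 2000 --out-dir out/zyp1oe_stats
```

prints

```
simulating 20 cells of wt_hybrid (female), seed 1
mean focus count 5.85; 46 chromatid COs
simulating 2000 cells of zyp1_hei10oe_hybrid (female), seed 1
mean focus count 39.15; 38656 chromatid COs
two-CO distance Mann-Whitney p = 0.996
mean CoC 0.996 (adjacent 0.988)
```

Reading: the wild-type coarsening run designates ~5.9 MLH1-like foci per
cell (five bivalents, close to the one-per-bivalent obligate-CO floor),
and 50% thinning transmits ~2.3 COs per chromatid set.  The *zyp1*
overexpressor null gives ~19.3 COs per chromatid set (38656/2000) and
twice that at the bivalent level.  Its distance distribution is
indistinguishable from the no-interference permutation
null (p ≈ 1) and its CoC curve is flat at ~1 — no interference, as
expected for independent placement.  For the coarsening genotypes the same
`stats` command shows CoC well below 1 at short inter-interval distances.

`meiocross reproduce --seed 0 --out-dir out/repro` runs a scaled-down
version of the whole model experiment (all hybrid genotype presets, both
sexes) and writes per-genotype focus-count, crossover and CoC tables.

The `synth` → `call` → `stats` chain exercises the sequencing side: plant
COs, genotype markers at shallow depth, recover the COs with the
sliding-window caller and push them through the same statistics.

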