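"""Built-in example configurations: karyotypes and genotype presets.

SC lengths are cytological quantities that must ultimately come from axis
tracing in the material under study; the values shipped here are editable
example values for a female Arabidopsis meiocyte (um), paired with the
public TAIR10 chromosome sizes (Mb).  Male meiocytes have ~1.6x longer SCs
at unchanged genomic lengths, which is how heterochiasmy enters the
coarsening model.

HEI10 dosage factors y: 2 (wild-type Col), 6 / 8 (heterozygous /
homozygous HEI10 overexpression in Col), 1.5 (wild-type Col/Ler hybrid,
reflecting the weaker Ler allele), 5.5 (heterozygous overexpression in the
hybrid).  *zyp1* presets are parameterized by the mean CO count per
transmitted chromatid set, apportioned across chromosomes by genomic
length.
"""

from __future__ import annotations

from .meiosis import Chromosome, GenotypeSpec, Karyotype, poisson_means_from_total

__all__ = [
    "FEMALE_KARYOTYPE",
    "MALE_SC_FACTOR",
    "male_karyotype",
    "DOSAGE_FACTORS",
    "ZYP1_CHROMATID_MEANS",
    "genotype_preset",
    "GENOTYPE_PRESETS",
]

FEMALE_KARYOTYPE = Karyotype(
    (
        Chromosome("chr1", 24.0, 30.43),
        Chromosome("chr2", 17.0, 19.70),
        Chromosome("chr3", 19.0, 23.46),
        Chromosome("chr4", 15.0, 18.59),
        Chromosome("chr5", 21.0, 26.98),
    )
)

MALE_SC_FACTOR = 1.6


def male_karyotype(female: Karyotype = FEMALE_KARYOTYPE) -> Karyotype:
    """Male karyotype: female SC lengths scaled by the male:female factor."""
    return female.scaled(MALE_SC_FACTOR)


DOSAGE_FACTORS = {
    "wt_col": 2.0,
    "hei10oe_het_col": 6.0,
    "hei10oe_homo_col": 8.0,
    "wt_hybrid": 1.5,
    "hei10oe_het_hybrid": 5.5,
}

# Mean COs per transmitted chromatid set for zyp1-background presets.
# zyp1 HEI10oe values are measured directly; plain-zyp1 values derive from
# wild-type hybrid means (female 19.6/6.4, male 14.7/3.1) times the
# reported zyp1 fold changes (2.3 female, 1.5 male).
ZYP1_CHROMATID_MEANS = {
    ("zyp1_hybrid", "female"): 7.0,
    ("zyp1_hybrid", "male"): 7.1,
    ("zyp1_hei10oe_hybrid", "female"): 19.6,
    ("zyp1_hei10oe_hybrid", "male"): 14.7,
}


def genotype_preset(
    name: str, sex: str = "female", karyotype: Karyotype | None = None
) -> GenotypeSpec:
    """Look up a preset genotype by name and sex.

    Coarsening genotypes: wt_col, hei10oe_het_col, hei10oe_homo_col,
    wt_hybrid, hei10oe_het_hybrid.  zyp1 genotypes: zyp1_hybrid,
    zyp1_hei10oe_hybrid (these need a karyotype to apportion the Poisson
    means; defaults to the shipped female karyotype).
    """
    if name in DOSAGE_FACTORS:
        return GenotypeSpec(name=name, dosage_factor=DOSAGE_FACTORS[name], sex=sex)
    key = (name, sex)
    if key in ZYP1_CHROMATID_MEANS:
        kt = karyotype if karyotype is not None else FEMALE_KARYOTYPE
        means = poisson_means_from_total(ZYP1_CHROMATID_MEANS[key], kt)
        return GenotypeSpec(name=name, zyp1=True, sex=sex, poisson_means=means)
    raise KeyError(f"unknown genotype preset: {name!r} (sex={sex!r})")


GENOTYPE_PRESETS = sorted(
    set(DOSAGE_FACTORS) | {name for name, _ in ZYP1_CHROMATID_MEANS}
)
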