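# Example meiocross configuration.
#
# SC lengths (um) are cytological inputs: replace them with measurements
# for your material.  Genomic lengths are in Mb (TAIR10 sizes here).
# The shipped values describe a female meiocyte; pass --sex male on the
# command line (or scale sc_length_um by ~1.6) for male meiosis.

karyotype:
  chr1: {sc_length_um: 24.0, genomic_length_mb: 30.43}
  chr2: {sc_length_um: 17.0, genomic_length_mb: 19.70}
  chr3: {sc_length_um: 19.0, genomic_length_mb: 23.46}
  chr4: {sc_length_um: 15.0, genomic_length_mb: 18.59}
  chr5: {sc_length_um: 21.0, genomic_length_mb: 26.98}

genotypes:
  wt_hybrid:
    dosage_factor: 1.5         # HEI10 dosage factor y
    sex: female
  hei10oe_het_hybrid:
    dosage_factor: 5.5
    sex: female
  zyp1_hybrid_female:
    zyp1: true
    sex: female
    poisson_means:             # mean COs per chromatid, per chromosome
      chr1: 1.79
      chr2: 1.16
      chr3: 1.38
      chr4: 1.09
      chr5: 1.58

# Optional solver overrides (defaults shown; dt_safety 0.25 is the fast
# Monte-Carlo profile, 0.05 the high-accuracy default).
coarsening:
  dt_safety: 0.05
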