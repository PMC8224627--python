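# Default HBB-locus variant panel.
#
# Coordinates are GRCh38 chromosome 11 (1-based). Classification logic never
# depends on absolute positions -- only on ids and alleles -- so coordinate
# errors are confined to VCF record matching, which also falls back to the id.
#
# classes: HBS (sickle), HBD (HbD-Punjab), BETA0 / BETA_PLUS / BETA_PLUS_PLUS
# (beta-thalassemia alleles by residual beta-globin output), TAG_SNP
# (haplotype-defining SNPs of the beta-globin gene cluster).

variants:
  - id: rs334
    hgvs: "c.20A>T"
    chrom: "11"
    pos: 5227002
    ref: T
    alt: A
    class: HBS

  # HbD-Punjab: the only common HbD allele in the Arabian Gulf region.
  - id: rs33946267
    hgvs: "c.364G>C"
    chrom: "11"
    pos: 5226774
    ref: C
    alt: G
    class: HBD

  # Beta-thalassemia alleles (legacy ids; HGVS strings recorded verbatim).
  - id: "IVS-1, -25del"
    hgvs: "c.93-22_95del"
    chrom: "11"
    pos: 5226821
    ref: CTTTCTTTCAGGGCAATAATGATACA
    alt: C
    class: BETA0
  - id: "IVS-II-1"
    # Legacy literature also writes this allele as IVS-II-1 (G->A); the HGVS
    # string below is kept verbatim and the alleles follow it.
    hgvs: "c.315+1G>T"
    chrom: "11"
    pos: 5226576
    ref: G
    alt: T
    class: BETA0
  - id: "IVS-I-110"
    hgvs: "c.93-21G>A"
    chrom: "11"
    pos: 5226820
    ref: G
    alt: A
    class: BETA_PLUS
  - id: "IVS-I-1"
    hgvs: "c.92+1G>T"
    chrom: "11"
    pos: 5226929
    ref: G
    alt: T
    class: BETA0
  - id: "IVS-I-5"
    hgvs: "c.92+5G>C"
    chrom: "11"
    pos: 5226925
    ref: G
    alt: C
    class: BETA_PLUS
  - id: "CD39"
    hgvs: "c.118C>T"
    chrom: "11"
    pos: 5226774
    ref: C
    alt: T
    class: BETA0
  - id: "CD8"
    hgvs: "c.25_26delTT"
    chrom: "11"
    pos: 5226996
    ref: ATT
    alt: A
    class: BETA0
  - id: "CD8/9"
    hgvs: "c.27dupG"
    chrom: "11"
    pos: 5226994
    ref: G
    alt: GG
    class: BETA0
  - id: "CD36/37"
    hgvs: "c.112delA"
    chrom: "11"
    pos: 5226911
    ref: CA
    alt: C
    class: BETA0
  - id: "CD31"
    hgvs: "c.92G>C"
    chrom: "11"
    pos: 5226930
    ref: G
    alt: C
    class: BETA0
  - id: "CD41/42"
    hgvs: "c.126_129delCTTT"
    chrom: "11"
    pos: 5226892
    ref: ACTTT
    alt: A
    class: BETA0
  # Classed beta++ on phenotypic grounds (mild, near-AS presentation); some
  # tabulations class it as plain beta+ -- edit the class here to revert.
  - id: "IVS-I-6"
    hgvs: "c.92+6T>C"
    chrom: "11"
    pos: 5226924
    ref: T
    alt: C
    class: BETA_PLUS_PLUS
  - id: "CD 82/83"
    hgvs: "c.251delG"
    chrom: "11"
    pos: 5226552
    ref: AG
    alt: A
    class: BETA0

  # Haplotype-tag SNPs, in panel order.
  - id: rs968857
    hgvs: ""
    chrom: "11"
    pos: 5242453
    ref: T
    alt: C
    class: TAG_SNP
  - id: rs10128556
    hgvs: ""
    chrom: "11"
    pos: 5263683
    ref: C
    alt: T
    class: TAG_SNP
  - id: rs28440105
    hgvs: ""
    chrom: "11"
    pos: 5248329
    ref: C
    alt: A
    class: TAG_SNP
  # XmnI -158 HBG2 polymorphism; reported variously as C>T or G>A by strand.
  # The encoding table below is the single audited place where physical
  # alleles are translated to pattern symbols.
  - id: rs7482144
    hgvs: ""
    chrom: "11"
    pos: 5254939
    ref: G
    alt: A
    class: TAG_SNP
  - id: rs3834466
    hgvs: ""
    chrom: "11"
    pos: 5290270
    ref: T
    alt: TT
    class: TAG_SNP

tag_panel:
  # Fixed column order of the 5-symbol haplotype patterns.
  order: [rs968857, rs10128556, rs28440105, rs7482144, rs3834466]
  # Physical allele -> pattern symbol, per SNP. For rs3834466 the shorter
  # allele (T) is symbol "1" and the duplication (TT) is symbol "2".
  encoding:
    rs968857:  {T: "T", C: "C"}
    rs10128556: {C: "C", T: "T"}
    rs28440105: {C: "C", A: "A"}
    rs7482144: {G: "G", A: "A"}
    rs3834466: {T: "1", TT: "2"}

# Canonical 5-symbol patterns of the beta-S gene-cluster haplotypes.
# ATP-I/II/III are the named recurrent atypical patterns; any other pattern
# is reported as ATP(<pattern>).
haplotypes:
  AI: TTCA2
  SEN: TTCA1
  BEN: TTCG1
  BAN: CCCG1
  CAM: TCAG1
  ATP-I: CCCG2
  ATP-II: TTCG2
  ATP-III: TCCG2
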