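# Default targeted BSAS panel: proximal promoters / first exons of seven
# sex-related genes of a barramundi (Lates calcarifer) gonad methylation study.
# Coordinates are TSS-relative with no position zero; lengths are the
# naive signed subtraction end - start.  group_methylation holds the
# study's per-group amplicon means +/- SD (percent), used as simulation
# ground truth.  Amplicon sequences are not shipped; the simulator
# synthesizes sequences honouring cpg_count and the primer cores.
spacer_length: 100
amplicons:
  - gene: dmrt1
    amplicon_id: dmrt1 (1)
    start: -575
    end: -305
    length: 270
    cpg_count: 5
    primers:
      name_fwd: D1-BS-P-F1Seq
      name_rev: D1-BS-P-R1Seq
      core_fwd: GTTGATTAGGATTTGTGTTTTAAAGT
      core_rev: TAAAACCTATTATTTCATATAAACATATTT
  - gene: dmrt1
    amplicon_id: dmrt1 (2)
    start: -255
    end: 173
    length: 428
    cpg_count: 17
    primers:
      name_fwd: D1-BS-P-F2Seq
      name_rev: D1-BS-CDS-R1Seq
      core_fwd: AAATTAAGTGTAGTAGAGTGATGTTAT
      core_rev: AAACACTAACAATCCCTCCAATTAC
  - gene: nr5a2
    amplicon_id: nr5a2 (1)
    start: -450
    end: -148
    length: 302
    cpg_count: 10
    primers:
      name_fwd: sf1-BS-F1.Seq
      name_rev: sf1-BS-R1.Seq
      core_fwd: TTTTGTGTGTTTTTATTTGTTTGTG
      core_rev: TTCTTTCTCAATTCTTTTAAACTTTTAAAT
  - gene: nr5a2
    amplicon_id: nr5a2 (2)
    start: -79
    end: 115
    length: 194
    cpg_count: 8
    primers:
      name_fwd: sf1-BS-F2.Seq
      name_rev: sf1-BS-R2.Seq
      core_fwd: GGAAAAGAGATTGTTTAGTATAGTAATAGA
      core_rev: TAAAAACACTAACCTTACAACTCTC
  - gene: cyp19a1
    amplicon_id: cyp19a1
    start: -107
    end: 160
    length: 267
    cpg_count: 8
    primers:
      name_fwd: CYP19-BS-F.Seq
      name_rev: CYP19-BS-R.Seq
      core_fwd: TGGTTGTTTATAAAGGGGAAGTTT
      core_rev: CCAACAACAAACAAACAAATAACATA
  - gene: amh
    amplicon_id: amh
    start: -258
    end: 83
    length: 341
    cpg_count: 6
    primers:
      name_fwd: amh-F.Seq
      name_rev: amh-R.Seq
      core_fwd: TGGTGTGTGTTTGAATTAGAAAATT
      core_rev: CCATAAAAAACATAAAAAACCACAC
  - gene: foxl2
    amplicon_id: foxl2 (1)
    start: -282
    end: -27
    length: 255
    cpg_count: 9
    primers:
      name_fwd: F2-BS-P-F1.Seq
      name_rev: F2-BS-P-R1.Seq
      core_fwd: AAAGGGTTGGGTTTATTGATTTATAA
      core_rev: ATCCAAATACCAACAAACAAAACTT
  - gene: foxl2
    amplicon_id: foxl2 (2)
    start: 374
    end: 682
    length: 308
    cpg_count: 18
    primers:
      name_fwd: F2-BS-CDS-F1.Seq
      name_rev: F2-BS-CDS-R1.Seq
      core_fwd: AGTTTGTGAGGATATGTTTGAGAAG
      core_rev: CCATACTCTACACCCTAAAATAAAAATTAT
  - gene: sox8
    amplicon_id: sox8 (1)
    start: -195
    end: 173
    length: 368
    cpg_count: 26
    primers:
      name_fwd: S8-BS-P-F2.Seq
      name_rev: S8-BS-R.Seq
      core_fwd: TAAATAGGGAAGTAGAAGGGAAATAA
      core_rev: AAATCCAATTTCTTACCCAAACC
  - gene: sox8
    amplicon_id: sox8 (2)
    start: 151
    end: 504
    length: 353
    cpg_count: 20
    primers:
      name_fwd: S8-BS-CDS-F1.Seq
      name_rev: S8-BS-R2.Seq
      core_fwd: GTTTGGGTAAGAAATTGGATTT
      core_rev: TAACTACTCTATTATTTTCATTTAATACAA
  - gene: sox9
    amplicon_id: sox9
    start: -130
    end: 214
    length: 344
    cpg_count: 19
    primers:
      name_fwd: S9-BS-F2.Seq
      name_rev: S9-BS-R2.Seq
      core_fwd: ATTTAGTTTTGTTAGTTAAGTTGTG
      core_rev: TACAAACAAAAAACTTTTCTTCTTC

group_methylation:
  dmrt1 (1):
    captive_testes: [41.2, 17.1]
    wild_testes: [67.8, 20.2]
    captive_ovaries: [58.6, 14.6]
    wild_ovaries: [71.0, 12.3]
  dmrt1 (2):
    captive_testes: [6.8, 6.9]
    wild_testes: [6.5, 7.3]
    captive_ovaries: [17.0, 9.5]
    wild_ovaries: [16.3, 10.4]
  nr5a2 (1):
    captive_testes: [10.2, 1.3]
    wild_testes: [10.7, 1.4]
    captive_ovaries: [16.2, 4.8]
    wild_ovaries: [20.6, 4.4]
  nr5a2 (2):
    captive_testes: [12.9, 2.2]
    wild_testes: [13.4, 1.1]
    captive_ovaries: [59.3, 12.4]
    wild_ovaries: [59.3, 12.9]
  cyp19a1:
    captive_testes: [92.5, 2.0]
    wild_testes: [88.0, 8.2]
    captive_ovaries: [44.1, 8.7]
    wild_ovaries: [54.0, 8.9]
  amh:
    captive_testes: [94.0, 1.4]
    wild_testes: [76.6, 3.0]
    captive_ovaries: [59.5, 2.2]
    wild_ovaries: [46.0, 2.7]
  foxl2 (1):
    captive_testes: [3.7, 0.7]
    wild_testes: [6.9, 0.6]
    captive_ovaries: [5.8, 0.8]
    wild_ovaries: [4.0, 0.7]
  foxl2 (2):
    captive_testes: [6.4, 0.9]
    wild_testes: [8.61, 0.9]
    captive_ovaries: [7.55, 1.1]
    wild_ovaries: [8.5, 1.0]
  sox8 (1):
    captive_testes: [1.5, 1.2]
    wild_testes: [2.0, 1.0]
    captive_ovaries: [2.3, 1.3]
    wild_ovaries: [2.4, 2.6]
  sox8 (2):
    captive_testes: [7.1, 1.2]
    wild_testes: [10.0, 1.7]
    captive_ovaries: [9.1, 1.5]
    wild_ovaries: [10.5, 2.5]
  sox9:
    captive_testes: [0.8, 0.8]
    wild_testes: [1.1, 0.9]
    captive_ovaries: [1.1, 0.7]
    wild_ovaries: [1.3, 0.7]
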