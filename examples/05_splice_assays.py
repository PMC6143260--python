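"""Sex-specific splice variants and virtual RT-PCR sex-typing.

The toy dmrt1-like gene loses its DM-domain exon in the ovary variant;
the toy cyp19a1-like gene shortens exons 1 and 2 in testis variants
(196->163 bp and 151->101 bp) and occasionally skips exon 3.  Two
end-point assays then type a transcript set: a DM-domain amplicon
(575 bp, testis-only) and an exon-1-boundary amplicon (207 bp,
ovary-only).
"""

from bsaskit.simulate import simulate_isoforms
from bsaskit.splice import domain_present, exon_diff, sex_type_transcripts, virtual_pcr

toys = simulate_isoforms(seed=0)

print("splice events relative to each reference gene model:")
for name, iso in toys.isoforms.items():
    model = toys.models[name.split("_")[0]]
    events = exon_diff(iso, model)
    desc = "; ".join(f"{e.kind}({e.exon_ref}, {e.delta:+d} bp)" for e in events)
    print(f"  {name:<18} {desc or 'matches the reference'}")

dm = toys.models["dmrt1"]
print(f"\nDM domain present: testis "
      f"{domain_present(toys.isoforms['dmrt1_testis'], dm, 'DM')}, "
      f"ovary {domain_present(toys.isoforms['dmrt1_ovary'], dm, 'DM')}")

male, female = toys.assay_primers["dmrt1_male"], toys.assay_primers["cyp19a1_female"]
print(f"male assay on testis transcript: "
      f"{virtual_pcr(male, toys.transcripts['dmrt1_testis']).product} bp; "
      f"on ovary: {virtual_pcr(male, toys.transcripts['dmrt1_ovary']).product}")
print(f"female assay on ovary transcript: "
      f"{virtual_pcr(female, toys.transcripts['cyp19a1_ovary']).product} bp; "
      f"on testis: {virtual_pcr(female, toys.transcripts['cyp19a1_testis_a']).product}")

t = toys.transcripts
print(f"\nsex-typing: testis transcript set -> "
      f"{sex_type_transcripts([t['dmrt1_testis'], t['cyp19a1_testis_a']], male, female)}; "
      f"ovary set -> "
      f"{sex_type_transcripts([t['dmrt1_ovary'], t['cyp19a1_ovary']], male, female)}")
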