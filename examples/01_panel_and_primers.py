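"""Load the bundled amplicon panel and validate its bisulfite primers.

The panel targets proximal promoters / first exons of seven sex-related
genes with 11 amplicons.  Amplicon sizes come from TSS-relative
coordinates (no position zero); primers must carry no C (forward) / no G
(reverse) after overhang stripping, because bisulfite conversion makes
every unmethylated C read as T.
"""

from bsaskit import cpg_density, load_default_panel, validate_bisulfite_primers

panel = load_default_panel()
print(f"panel: {len(panel)} amplicons, {panel.total_cpg_count} CpG sites, "
      f"{panel.total_length} bp targeted")

print(f"\n{'amplicon':<12} {'span':>12} {'bp':>5} {'CpG':>4} {'CpG/100bp':>10} primers_ok")
for amp in panel:
    ok = validate_bisulfite_primers(amp.primers).bisulfite_compatible
    print(f"{amp.amplicon_id:<12} ({amp.start:>5},{amp.end:>5}) {amp.length:>5} "
          f"{amp.declared_cpg_count:>4} {cpg_density(amp):>10.2f} {ok}")

# the mapping reference: fully converted amplicons separated by 100-N spacers
materialized = panel.with_sequences(seed=0)
ref, offsets = materialized.build_reference()
print(f"\nconverted mapping reference: {len(ref)} bp "
      f"({panel.total_length} bp of amplicons + {100 * (len(panel) - 1)} bp of N spacers)")
print("high CpG density marks island-like amplicons (sox8/foxl2), which the "
      "study design expects to be hypomethylated in both sexes.")
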