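"""Build a reporter construct and derive its post-cut reference and window.

The two-cut reporter carries a killer exon between inverted I-SceI sites
inside the intron of a split GFP gene.  Double digestion excises the killer
exon; the two retained intron flanks are the reference every junction read is
interpreted against, and the rescue primers bound how large a deletion can
still be amplified and observed.
"""

from nhejscar import derive_cut_reference, detection_window, make_construct

construct, cutref = make_construct(
    seed=0,
    intron_len_5p=400,
    intron_len_3p=350,
    primer_offset_5p=300,
    primer_offset_3p=250,
    planted_repeats=[(7, 60, 45)],
)
window = detection_window(construct, cutref)

print(f"construct: {construct.name}, {len(construct.sequence)} bp")
print(f"excised interval (killer exon + cut sites): {construct.excised_interval}")
print(f"left flank:  {len(cutref.left_flank)} bp")
print(f"right flank: {len(cutref.right_flank)} bp")
print(f"perfect-rejoin product: {len(cutref.joined)} bp")
print(f"detection window: {window.max_del_5prime} bp (5') / {window.max_del_3prime} bp (3')")
print()
print("A deletion larger than the window on either side of the break cannot be")
print("rescued by the primers, so it is invisible to the assay; every statistic")
print("downstream is conditioned on this window.")
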