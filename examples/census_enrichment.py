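"""Enrichment of disease variants by structural region.

Feeds the packaged six-disease interaction-network census through the
enrichment statistics: O/E ratios compare where disease variants fall
against the residue composition, and the odds ratio asks whether a
disease variant prefers interfaces over the rest of the surface.
"""

from dockint import summarize_census, table2_census

for context in ("structural", "docking", "combined"):
    s = summarize_census(table2_census(context))
    oe = s["oe_disease"]
    orr = s["or_interface_vs_surface"]
    print(f"[{context}]")
    print(f"  O/E disease core/interface/surface: "
          f"{oe['core']:.2f} / {oe['interface']:.2f} / "
          f"{oe['non_interface']:.2f}")
    print(f"  OR interface vs non-interacting surface: "
          f"{orr.odds_ratio:.2f} (p = {orr.p_value:.3g})")

s = summarize_census(table2_census("combined"))
print(f"[combined] hot-spot disease variants: O/E "
      f"{s['oe_hotspot_disease']:.2f}, OR vs surface "
      f"{s['or_hotspot_vs_surface'].odds_ratio:.2f}")
print()
print("O/E > 1 marks over-representation: disease variants concentrate in")
print("the buried core; once docking models fill in missing interfaces")
print("(docking/combined), interfaces are preferred over the rest of the")
print("surface (OR > 1).")
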