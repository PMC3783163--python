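# LI integrase C-terminal-domain annotation scheme, in deposit numbering.
# RD: recombinase domain; ZD: zinc-ribbon domain; CC: coiled-coil insertion
# (a carve-out inside the ZD span).  Anchors are single residues used as
# geometric reference points: ZD_anchor closes the helix preceding the ZD
# beta-sheet (Ala338); CC_tip is the turn residue at the far end of the
# coiled-coil hairpin (Tyr374).
name: li_ctd
domains:
  RD: [133, 264]
  ZD: [265, 452]
  CC: [342, 416]
anchors:
  ZD_anchor: 338
  CC_tip: 374
metadata:
  zinc_cysteines: [274, 277, 302, 314]
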