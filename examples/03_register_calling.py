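"""Call coiled-coil heptad registers, including the -4 overwinding model.

Scores all seven register phases of each linker (fraction of a/d positions
occupied by stabilisers: hydrophobics plus Asn), labels the top phase
"inhibiting" and the runner-up "stimulating", and, for -4 linkers, finds the
breakpoint of the locally overwound stretch.
"""

from padckit import (FamilySpec, build_template, call_registers,
                     extract_linker_sequence, compute_linker)

for rel in (0, 7, -4, 2):
    tpl = build_template(FamilySpec(f"fam{rel:+d}", relative_linker_length=rel),
                         rng_seed=42)
    ann = compute_linker(tpl.sequence, tpl.anchor_index)
    linker = extract_linker_sequence(tpl.sequence, ann)
    call = call_registers(linker, ann.relative_length)
    scores = " ".join(f"{s:.2f}" for s in call.phase_scores)
    print(f"rel {rel:+3d}  linker {linker}")
    print(f"         phase scores [{scores}]  inhibiting={call.inhibiting_phase} "
          f"stimulating={call.stimulating_phase} "
          f"breakpoint={call.overwind_breakpoint} class={call.regulatory_class}")
# A div7 linker keeps a perfect register (score 1.0 -> switch_capable); the
# -4 linker reaches 1.0 only through the overwinding path (frame shift of +4
# upstream of the breakpoint); the +2 linker cannot stabilise any single
# register (impaired_cc).
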