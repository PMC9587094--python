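"""Classify sequences and measure the sensor-effector linker.

Runs the motif screen (PadC / PadC-EAL / non-member) and the linker-length
statistic — residues strictly between the PHY-helix anchor and the D of
DXLT, relative to the 28-residue reference — on a small synthetic dataset.
"""

from padckit import (AnchorSpec, annotate_sequences, default_demo_specs,
                     generate_dataset)

ds = generate_dataset(default_demo_specs(n_members=2, within_divergence=0.15),
                      global_seed=42)
ann = annotate_sequences(ds.sequences, ds.alignment,
                         AnchorSpec(ds.reference_id, ds.reference_anchor_1based))

cols = ["sequence_id", "class", "pde_active", "anchor_1based", "dxlt_1based",
        "abs_linker_len", "rel_linker_len", "linker_family"]
print(ann[cols].to_string(index=False))
# abs_linker_len counts residues between anchor and DXLT (both excluded);
# rel_linker_len subtracts the 28-residue reference; linker_family bins into
# div7 (multiples of seven), minus4, plus2 or other.
match = (ann.set_index("sequence_id")["rel_linker_len"]
         == ds.truth.set_index("sequence_id")["rel_linker_len"]).mean()
print(f"\nrecovered relative linker lengths match the planted truth for "
      f"{100 * match:.0f}% of sequences")
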