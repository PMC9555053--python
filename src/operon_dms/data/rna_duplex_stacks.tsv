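# Nearest-neighbor RNA/RNA duplex stack free energies (kcal/mol, 37 C).
# Watson-Crick stacks follow standard Turner-style helix parameters; any
# stack involving a G-U wobble pair uses the single representative value in
# the wobble_stack row. "stack" is top strand 5'->3' over bottom strand
# 3'->5' (first top base pairs first bottom base).
key	value
AA/UU	-0.93
AU/UA	-1.10
UA/AU	-1.33
CU/GA	-2.08
CA/GU	-2.11
GU/CA	-2.24
GA/CU	-2.35
CG/GC	-2.36
GG/CC	-3.26
GC/CG	-3.42
wobble_stack	-1.30
initiation	4.09
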