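# Binding-site boundary schemes: five sites S0 (extracellular) to S4
# (intracellular), each delineated by two rings of four oxygen atoms.
# Each ring is [author residue number, atom name], resolved in all four
# subunits. Schemes are configuration, not code: override freely.
herg:
  sf_residue_range: [623, 629]
  sites:
    S0: [[627, O], [626, O]]
    S1: [[626, O], [625, O]]
    S2: [[625, O], [624, O]]
    S3: [[624, O], [623, O]]
    S4: [[623, O], [623, OG1]]
kcsa:
  sf_residue_range: [74, 80]
  sites:
    S0: [[79, O], [78, O]]
    S1: [[78, O], [77, O]]
    S2: [[77, O], [76, O]]
    S3: [[76, O], [75, O]]
    S4: [[75, O], [75, OG1]]
# Pseudo-atom filter written by sfstates.synthetic: one carbonyl-oxygen ring
# per residue 623..628, extracellular ring first.
synthetic:
  sf_residue_range: [623, 628]
  sites:
    S0: [[628, O], [627, O]]
    S1: [[627, O], [626, O]]
    S2: [[626, O], [625, O]]
    S3: [[625, O], [624, O]]
    S4: [[624, O], [623, O]]
# Pseudo-atom KcsA-like stand-in filter written by sfstates.synthetic
# (reference_structures): canonical T75-OG1 .. G79-O ladder.
synthetic_kcsa:
  sf_residue_range: [75, 79]
  sites:
    S0: [[79, O], [78, O]]
    S1: [[78, O], [77, O]]
    S2: [[77, O], [76, O]]
    S3: [[76, O], [75, O]]
    S4: [[75, O], [75, OG1]]
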