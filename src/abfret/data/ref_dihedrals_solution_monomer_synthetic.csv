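# Synthetic stand-in reference set: core (residues 17-21) backbone dihedrals
# of a partially folded solution-phase monomer with a helical 12-28 region.
# Generated programmatically (helical cluster, seeded); NOT extracted from any
# deposited structure.
# phi_deg,psi_deg
-50.4,-65.3
-53.6,-41.0
-60.5,-47.5
-66.1,-39.8
-65.3,-39.4
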