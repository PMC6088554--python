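# Synthetic stand-in reference set: core (residues 17-21) backbone dihedrals
# of amyloid fibril beta-strands (five residues x three chains).
# Generated programmatically (beta cluster, seeded); NOT extracted from any
# deposited structure.
# phi_deg,psi_deg
-113.8,144.6
-137.2,125.7
-127.3,143.8
-109.6,129.6
-140.0,147.2
-131.3,121.5
-131.0,127.6
-150.1,137.2
-126.7,148.1
-148.1,133.7
-112.6,136.1
-150.1,157.0
-128.4,147.8
-133.3,137.8
-126.8,130.2
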