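"""Design a junction-targeting enrichment panel with padlock probes.

From discovered junctions, selects circles at least 300 nt long (one per
transcript, highest read support wins), builds junction-spanning amplicons
(60 nt per side of the back-splice), places linear-isoform controls 300 nt
away on the same transcript, samples 15 unsupported junctions as negative
controls, and designs a padlock probe with a unique 4-nt barcode for every
junction target.
"""

from collections import Counter

from circscreen import (
    annotate_exon_boundaries,
    call_backsplice_junctions,
    design_panel,
    make_toy_annotation,
    simulate_backsplice_reads,
)
from circscreen.simulate import SimConfig

config = SimConfig(seed=42)
genome, transcripts, planted = make_toy_annotation(config)
records, _, _ = simulate_backsplice_reads(transcripts, planted, None, config)
junctions = annotate_exon_boundaries(
    call_backsplice_junctions(records, genome), transcripts
)

targets, probes, codebook = design_panel(junctions, transcripts, genome)

print("panel composition:", dict(Counter(t.target_class for t in targets)))
circ = next(t for t in targets if t.target_class == "circ")
print(f"\nexample circ amplicon {circ.target_id}")
print(f"  length {len(circ.sequence)} nt, junction at offset {circ.junction_offset}")
print(f"  sequence around junction: ...{circ.sequence[50:70]}...")

probe = next(p for p in probes if p.target_id == circ.target_id)
print(f"\npadlock probe for the same junction (barcode {probe.barcode}):")
print(f"  3' arm {probe.arm_3p}")
print(f"  5' arm {probe.arm_5p}")
# The amplicon reads straight through the back-splice (the junction sits at
# its center), so only junction-spanning molecules amplify; the probe arms
# hybridize to the cDNA on either side of the junction and ligate only on a
# perfect match, and the barcode identifies the target during in situ
# sequencing.
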