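"""Decode an in situ sequencing experiment and localize transcripts.

Simulates a 4-cycle, four-channel barcode image stack (9 targets with a
Hamming-distance-2 codebook, ~500 rolling-circle products over 20 DAPI
nuclei), then runs the full decode: top-hat spot detection, per-cycle base
calling (quality = max/sum, range 0.25-1), quality filtering at 0.45,
exact codebook matching, and nuclear/cytoplasmic assignment from the
segmented DAPI mask.
"""

from circscreen import assign_barcodes, decode_stack
from circscreen.insitu import DecodeParams
from circscreen.simulate import SimConfig, simulate_insitu_stack

targets = [f"gene{i}" for i in range(9)]
codebook = assign_barcodes(targets, min_pairwise_hamming=2, seed=7)
counts = {t: 55 for t in targets}
# planted localization: gene0 fully cytoplasmic ... gene8 fully nuclear
fractions = {t: i / 8 for i, t in enumerate(targets)}

config = SimConfig(seed=7, channel_noise=5.0)
stack, dapi, truth = simulate_insitu_stack(codebook, counts, fractions, config)

result, ratios, mask = decode_stack(stack, dapi, codebook, DecodeParams())

print(f"detected {len(result.signals)} RCPs over {mask.max()} nuclei; "
      f"{result.n_rejected_quality} below quality, "
      f"{result.n_unexpected} unexpected barcodes")
print(f"\n{'target':<8} {'barcode':<8} {'count':>5} {'nuclear ratio':>13} {'planted':>8}")
for t in targets:
    planted = (truth.query("target_id == @t")["compartment"] == "nuclear").mean()
    print(f"{t:<8} {codebook.target_to_barcode()[t]:<8} "
          f"{result.counts[t]:>5} {ratios.get(t, float('nan')):>13.3f} "
          f"{planted:>8.3f}")
# The nuclear ratio is the fraction of a target's decoded signals falling
# inside the DAPI mask; a nuclear-retained transcript approaches 1.0, a
# cytoplasmic circRNA approaches 0.0, and the measured column tracks the
# planted fractions.
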