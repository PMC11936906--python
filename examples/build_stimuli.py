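"""Build the six motif-condition stimuli from one synthetic motif.

Synthesizes a four-syllable zebra-finch-like motif, extracts ramped
syllable tokens, and assembles an 8-motif song bout under each condition.
All conditions share the same timing skeleton, so the durations agree;
the manipulated fraction shows how much of the bout each condition touches.
"""

import numpy as np

from finchcall import (
    BoutSpec,
    RenditionJitter,
    build_bout,
    counterbalance_orders,
    example_motif_spec,
    manipulated_fraction,
    template_from_motif_spec,
)

template = template_from_motif_spec(
    example_motif_spec(n_syllables=4),
    RenditionJitter(duration_cv=0.05, f0_cv=0.02, level_sd=1.0, seed=7),
    n_renditions=4,
)
print(f"template: {template.n_syllables} syllables, "
      f"{len(template.rendition_bank)} renditions, {template.rate} Hz")

for condition in (
    "FIXED", "SHUFFLED", "REVERSAL", "RENDITION",
    "FIRST_MOTIF_REVERSAL", "LAST_MOTIF_REVERSAL",
):
    wave, ann = build_bout(template, BoutSpec(condition, n_motifs=8, seed=1))
    print(
        f"{condition:<22s} bout {wave.duration:6.3f} s, "
        f"{len(ann)} syllable slots, reversed fraction "
        f"{manipulated_fraction(ann):.3f}"
    )

print("\ncounterbalanced presentation orders (cyclic Latin square):")
for i, order in enumerate(
    counterbalance_orders(["FIXED", "REVERSAL", "SHUFFLED", "RENDITION"])
):
    print(f"  version {i}: {' -> '.join(order)}")
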