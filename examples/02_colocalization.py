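"""Quantify the percent of microtubule area decorated by a second channel.

Simulates a two-channel image in which exactly 25% of microtubule pixels
carry signal in channel 2 (in contiguous stretches, the way a
microtubule-associated protein decorates), then recovers that share from
the rendered, noisy images by per-channel Otsu masks.
"""

import mtquant as mq

params = mq.ColocSimParams(decorated_fraction_true=0.25, seed=7)
sim = mq.simulate_coloc_image(params)
result = mq.coloc_percent(sim.channel1, sim.channel2)

print(f"ground-truth decorated fraction: "
      f"{sim.decorated_fraction_realized:.3f}")
print(f"measured: {result.percent:.1f}% of {result.mt_area} microtubule "
      f"pixels overlap the channel-2 mask ({result.overlap_area} px)")

# The percent is area overlap restricted to the microtubule mask, so
# off-microtubule pools of the second channel (e.g. nuclear signal) cannot
# inflate it.
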