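"""Stimulation protocol arithmetic: iTBS vs 10-Hz rTMS.

Builds both bilateral-M1 protocols and derives their pulse totals and
per-side session lengths from the train structure.
"""

from tmsreact import build_protocol

for kind in ("iTBS", "rTMS10"):
    proto = build_protocol(kind)
    times = proto.train_pulse_times()
    print(f"{kind}: {proto.sides} sides x {proto.trains_per_side} trains x "
          f"{proto.pulses_per_train} pulses = {proto.total_pulses} pulses")
    print(f"  one train spans {times[-1]:.2f} s; "
          f"one side takes {proto.duration_per_side / 60:.1f} min")

# Both protocols reach the same 1200-pulse dose through very different
# temporal structures: iTBS packs 50-Hz triplet bursts into 2-s trains,
# the 10-Hz protocol spreads 30-pulse trains over 40-s intervals.
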