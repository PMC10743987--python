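"""Rodent EKG intervals from annotated fiducials, with Bazett correction.

Four consecutive beats are averaged before computing intervals, and the
rate-corrected QTc/JTc use Bazett's formula (QT / sqrt(RR in seconds)).
"""

import dataclasses

from ecckymo import EkgBeat, average_beats, compute_intervals

# four consecutive annotated beats of a mouse EKG (times in ms)
beats = [
    EkgBeat(p_onset=0.0 + j, q_onset=32.0 + j, r_peak=36.5 + j,
            qrs_end=42.0 + j, t_peak=55.0 + j, t_end=82.0 + j,
            rr_ms=150.0 + 2 * j)
    for j in (0.0, 0.4, -0.3, 0.1)
]

avg = average_beats(beats)
iv = compute_intervals(avg)
for name, value in dataclasses.asdict(iv).items():
    print(f"{name:16s} {value:8.2f}")

print("\nQT spans QRS onset to T-wave end; JT = QT - QRS isolates "
      "repolarization; QTc and JTc divide by sqrt(RR_s), so at the mouse "
      "RR of ~150 ms the corrected intervals are larger than the raw ones; "
      "heart rate is in beats per minute.")
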