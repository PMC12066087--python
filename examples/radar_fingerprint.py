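"""Export the radar ('therapeutic fingerprint') axes and render the plot.

The four axes are adjusted efficacy, engagement, evidence quality and
inverted safety (1 - penalty), all oriented so larger is better; the CSV is
the machine-readable surface, the PNG a convenience rendering.
"""

from pathlib import Path

from cdti import builtin_fixture, radar_data, score_record
from cdti.composite import RADAR_AXES
from cdti.plotting import plot_radar

cards = [score_record(builtin_fixture(name)) for name in ("reset_o", "ct132")]

print("axis,name,value")
for card in cards:
    for axis, value in zip(RADAR_AXES, radar_data(card)):
        print(f"{axis},{card.product_name},{value}")

out = Path("scratch")
out.mkdir(exist_ok=True)
plot_radar(cards, out / "fingerprint.png")
print(f"\nwrote {out / 'fingerprint.png'}")
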