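"""Network indicators on macro, micro and mezzo levels, plus the six
neighborhood-valence variants around two opposing anchor concepts.
"""

from camkit.indicators import (
    indicator_table,
    macro_indicators,
    mezzo_indicators,
    micro_indicators,
    neighborhood_valence,
)
from camkit.model import CAM, Concept, Connector

# a miniature bridged design: car cluster vs public-transport cluster
cam = CAM(
    cam_id="demo",
    concepts=(
        Concept(id="car", text="own car", valence=1, predefined=True),
        Concept(id="comfort", text="comfort", valence=2),
        Concept(id="parking", text="parking", valence=-1),
        Concept(id="pt", text="public transport", valence=-2, predefined=True),
        Concept(id="crowd", text="crowding", valence=-2),
        Concept(id="delay", text="delays", valence=-1),
    ),
    connectors=(
        Connector(id="e1", source="car", target="comfort", strength=2),
        Connector(id="e2", source="car", target="parking", strength=1),
        Connector(id="e3", source="pt", target="crowd", strength=3),
        Connector(id="e4", source="pt", target="delay", strength=2),
        Connector(id="e5", source="car", target="pt", strength=-3),
    ),
)

print(indicator_table(macro_indicators(cam)).to_string(index=False))
print()
print(indicator_table(micro_indicators(cam, ["car", "pt"])).to_string(index=False))
print()
print(indicator_table(mezzo_indicators(cam)).to_string(index=False))

print("\nNeighborhood mean valence (order 2) with the bridge temporarily removed,")
print("so each side is measured without the other leaking in:")
for focus in ("car", "pt"):
    v2 = neighborhood_valence(cam, focus, 2, removed_edges=[("car", "pt")])
    print(f"  around {cam.concept(focus).text!r}: {v2:+.2f}")
print("The negative value around 'public transport' vs the positive value "
      "around 'own car' quantifies the opposed attitudes.")
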