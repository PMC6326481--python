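"""Generate the synthetic benchmark landscape and write its fixtures.

Produces the two-epoch patch layers, coastline, multi-band scene, training
sets, ground-truth points and the planted-change ledger used by the
downstream analysis steps.
"""

import json
from pathlib import Path

from manglar import io, synth

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    script = synth.LandscapeScript(seed=SEED)
    land = synth.generate_landscape(script)

    io.write_patch_layer(land.layer_t, OUT / "patches_2004.geojson")
    io.write_patch_layer(land.layer_t1, OUT / "patches_2014.geojson")
    io.write_coastline(land.coastline, OUT / "coastline.geojson")
    io.write_scene(land.scene, OUT, stem="scene")
    (OUT / "ledger.json").write_text(json.dumps({
        "planted_area_m2": land.ledger.planted_area,
        "events": [list(e) for e in land.ledger.events],
    }, indent=2))

    print(f"seed {SEED}: {len(land.layer_t)} patches in 2004, "
          f"{len(land.layer_t1)} in 2014")
    print(f"cover {land.layer_t.total_area / 1e4:.1f} -> "
          f"{land.layer_t1.total_area / 1e4:.1f} ha "
          f"({100 * (land.layer_t1.total_area / land.layer_t.total_area - 1):+.1f} %)")
    print(f"coastline {land.coastline.total_length / 1e3:.1f} km; "
          f"fixtures in {OUT}")


if __name__ == "__main__":
    main()
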