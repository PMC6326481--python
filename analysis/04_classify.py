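"""Compare the three semi-automatic classification chains.

Runs MLC1 (whole scene), MLC2 (land/sea partitioned) and HYBRID
(NDVI-masked segmentation updated by MLC2) on the confusable benchmark
scene — deciduous tonality pulled toward mangrove, sea-surface algae
sharing the mangrove RGB signature — and scores each against the
generating truth points.
"""

import csv
from pathlib import Path

import numpy as np

from manglar import classification as C
from manglar import synth

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cs = synth.generate_confusable_scene(
        synth.LandscapeScript(seed=SEED, n_truth_points=2000))
    t = cs.scene.transform
    cols = np.clip(((cs.truth_points[:, 0] - t.x0) / t.px).astype(int),
                   0, cs.scene.shape[1] - 1)
    rows = np.clip(((t.y0 - cs.truth_points[:, 1]) / t.px).astype(int),
                   0, cs.scene.shape[0] - 1)

    def accuracy(grid):
        return 100.0 * float(np.mean(grid[rows, cols] == cs.truth_labels))

    m1 = C.mlc_classify(cs.scene, C.mlc_train(cs.training)) == "mangrove"
    land_mask = C.land_sea_mask(cs.scene, cs.coastline, cs.land_point)
    m2 = C.mlc2_classify(cs.scene, C.mlc_train(cs.training_land),
                         C.mlc_train(cs.training_sea), land_mask) == "mangrove"
    veg = C.vegetation_mask(C.ndvi(cs.scene))
    segs = C.region_grow_segment(cs.scene, veg, diff_threshold=0.75,
                                 min_size_px=200, band_names=("R", "G", "B"))
    hybrid = C.hybrid_select(segs, m2)

    table = [
        ("reference", 100.0),
        ("MLC2", accuracy(m2)),
        ("MLC1", accuracy(m1)),
        ("HYBRID", accuracy(hybrid)),
    ]
    with open(OUT / "classification_accuracy.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["method", "overall_accuracy_pct"])
        w.writerows([(m, round(a, 1)) for m, a in table])

    for method, acc in table:
        print(f"{method:>10}: {acc:5.1f} %")
    print("-> partitioning land and sea rescues the algae confusion; "
          "whole-segment selection commits the adjacent deciduous cover")
    print(f"table in {OUT / 'classification_accuracy.csv'}")


if __name__ == "__main__":
    main()
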