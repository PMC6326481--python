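"""Accuracy assessment of the benchmark map and a degraded competitor.

Buffers ground-truth sites (100 m radius, 3.14 ha), samples 500 points per
site, builds 2x2 confusion matrices against the generating truth, and
compares the two maps with the pooled two-proportion Z-test
(|Z| >= 1.96 marks a significant accuracy difference).
"""

from pathlib import Path

import numpy as np

from manglar import io, synth
from manglar.geometry import PatchLayer
from manglar.validation import (
    GroundTruthSite,
    classify_points,
    cohens_kappa,
    confusion,
    overall_accuracy,
    sample_validation_points,
    z_compare,
)

SEED = 11
N_POINTS = 500
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    land = synth.generate_landscape(synth.LandscapeScript(seed=SEED))
    rng = np.random.default_rng(SEED)

    # ground-truth sites centred on patch centroids (the field crew visits
    # candidate mangrove stands); the 100 m buffer mixes both classes
    sites = [GroundTruthSite(x=p.shapely.centroid.x, y=p.shapely.centroid.y,
                             label="mangrove")
             for p in land.layer_t1.patches[:40]]
    pts = np.vstack([sample_validation_points(s, N_POINTS, rng) for s in sites])
    truth = classify_points(land.layer_t1, pts)  # the generating map IS truth

    faithful = land.layer_t1
    degraded = PatchLayer(patches=faithful.patches[::3], crs=faithful.crs)

    results = {}
    for name, layer in (("faithful", faithful), ("degraded", degraded)):
        cm = confusion(layer, pts, truth)
        results[name] = {
            "n": cm.n,
            "correct": cm.correct,
            "confusion": cm.as_array().tolist(),
            "accuracy_pct": overall_accuracy(cm),
            "kappa": cohens_kappa(cm),
        }
        print(f"{name:>9}: accuracy {results[name]['accuracy_pct']:.1f} %, "
              f"kappa {results[name]['kappa']:.3f} (n={cm.n})")

    zc = z_compare(results["faithful"]["correct"], results["faithful"]["n"],
                   results["degraded"]["correct"], results["degraded"]["n"])
    results["z_faithful_vs_degraded"] = {"z": zc.z, "significant": zc.significant}
    print(f"two-proportion Z = {zc.z:.1f} -> "
          f"{'significant' if zc.significant else 'not significant'} at 5 %")

    io.write_report(results, OUT / "validation.json")
    print(f"report in {OUT / 'validation.json'}")


if __name__ == "__main__":
    main()
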