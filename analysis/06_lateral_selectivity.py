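"""Is the HNN's learned inhibition selective for similarly tuned units?

For randomly sampled neurons, plots the feedforward weights of their
most-inhibited targets (sorted by outgoing lateral weight) and reports
the top-k minus bottom-k feedforward-cosine statistic.
"""

import json
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from compcode.evaluation import display_scale, lateral_selectivity, weight_image
from compcode.experiment import ExperimentConfig, run_experiment, substream
from compcode.hnn import HNN

OUT = Path("results")


def main(seed: int = 1) -> None:
    cfg = ExperimentConfig(seed=seed)
    run_experiment(cfg, outdir=OUT / "experiment")  # ensures cached HNN
    hnn = HNN.load(OUT / "experiment" / "cache" / f"{cfg.digest()}_hnn_0.npz")

    panel, stat = lateral_selectivity(
        hnn, n_neurons=10, top_k=10, seed=substream(seed, "lateral")
    )
    with open(OUT / "lateral_selectivity.json", "w") as fh:
        json.dump({"statistic": stat, "panel": panel}, fh, indent=1)
    print(f"lateral selectivity statistic (top-10 minus bottom-10 cosine): "
          f"{stat:.3f}")

    fig, axes = plt.subplots(len(panel), 11, figsize=(11, len(panel)))
    for row, entry in zip(axes, panel):
        units = [entry["unit"]] + entry["targets"]
        for ax, j in zip(row, units):
            img = display_scale(weight_image(hnn.Wff_[j, :144], hnn.Wff_[j, 144:]))
            ax.imshow(img, cmap="gray", vmin=0, vmax=1)
            ax.set_axis_off()
        row[0].set_title("source", fontsize=6)
    fig.suptitle("Most-inhibited targets, sorted by outgoing lateral weight")
    figdir = OUT / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "lateral_selectivity.png", dpi=150, bbox_inches="tight")
    print(f"panel written to {figdir / 'lateral_selectivity.png'}")
    print("\nA positive statistic means neurons inhibit most strongly the")
    print("neurons whose feedforward weights resemble their own — the")
    print("anti-Hebbian rule stores response correlations as targeted")
    print("competition.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
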