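"""Binary PLS-DA ROC curves per platform and class pair.

Scores come from leave-one-out cross-validation over the pooled harvests;
the AUC summarises the separability of each provenance pairing on each
spectroscopic platform.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from honeyspec.config import default_pipeline, default_regions
from honeyspec.plsda import _rowspace, fit_pls, predict_response, roc_curve
from honeyspec.preprocess import fit_pipeline
from honeyspec.spectra_io import select_regions
from honeyspec.synthetic import default_config, generate

ROOT = Path(__file__).resolve().parents[1]
PAIRS = (("BA", "Cat"), ("BA", "Mis"), ("Cat", "Mis"))


def loo_scores(block, labels, pair, n_components=5):
    y = (labels == pair[1]).astype(float)
    z = _rowspace(block.intensities)
    scores = np.empty(len(y))
    for i in range(len(y)):
        mask = np.arange(len(y)) != i
        model = fit_pls(z[mask], y[mask], n_components)
        scores[i] = predict_response(model, z[i][None, :])[0]
    return scores, y


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2014)
    args = parser.parse_args()

    blocks, table = generate(default_config(args.seed)).averaged()
    frame = table.per_sample()

    rows = []
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, pair in zip(axes, PAIRS):
        idx = frame.index[frame.class_label.isin(pair)].to_numpy()
        labels = frame.class_label.to_numpy()[idx]
        for name in blocks:
            block = select_regions(blocks[name], default_regions(name)).take(idx)
            # row-wise steps only: per-fold centering happens inside the PLS fit
            prepped, _ = fit_pipeline(block, default_pipeline(name)[:-1])
            scores, y = loo_scores(prepped, labels, pair)
            curve = roc_curve(scores, y)
            rows.append({"pair": f"{pair[0]} vs {pair[1]}", "platform": name,
                         "auc": round(curve.auc, 4)})
            ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC {curve.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_title(f"{pair[0]} vs {pair[1]}")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", fontsize=8)

    tables = ROOT / "results" / "tables"
    figures = ROOT / "results" / "figures"
    tables.mkdir(parents=True, exist_ok=True)
    figures.mkdir(parents=True, exist_ok=True)
    auc_table = pd.DataFrame(rows).pivot(index="pair", columns="platform", values="auc")
    auc_table.to_csv(tables / "roc_auc.csv")
    fig.tight_layout()
    fig.savefig(figures / "roc_curves.png", dpi=120)
    print("LOO-CV ROC AUC per platform:")
    print(auc_table.to_string())
    print("\nThe BA/Mis pairing separates almost perfectly on every platform; "
          "pairings involving the heterogeneous Cat class are harder, and the "
          "Raman-like platform trails the other two.")


if __name__ == "__main__":
    main()
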