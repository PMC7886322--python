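"""Figure-style panels of the sweep outcomes (displacement and stress)."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_sweep"]

_ORDER = ["frictionless", "frictional_mu0.2", "frictional_mu0.4",
          "frictional_mu0.6", "frictional_mu0.8", "frictional_mu1", "bonded"]
_XLAB = ["0", "0.2", "0.4", "0.6", "0.8", "1.0", "bonded"]


def plot_sweep(table: pd.DataFrame, path=None):
    """Three-row panel per loaded sub-tendon: raw and normalised proximal
    soleus-face displacement and normalised mean von Mises stress versus the
    interface condition."""
    loads = sorted(table["loaded"].unique())
    models = sorted(table["model_id"].unique())
    rows = [("sol_face_displacement_mm", "SOL face displacement (mm)"),
            ("normalized_displacement", "normalised displacement"),
            ("mean_vm_normalized", "normalised mean von Mises")]
    fig, axes = plt.subplots(len(rows), len(loads),
                             figsize=(4 * len(loads), 3 * len(rows)),
                             squeeze=False)
    for j, load in enumerate(loads):
        for i, (col, label) in enumerate(rows):
            ax = axes[i][j]
            for mid in models:
                sub = table[(table["loaded"] == load)
                            & (table["model_id"] == mid)]
                sub = sub.set_index("interface").reindex(_ORDER)
                ax.plot(range(len(_ORDER)), sub[col], "o-",
                        label=f"Model {mid}")
            ax.set_xticks(range(len(_ORDER)), _XLAB, rotation=45)
            if i == 0:
                ax.set_title(f"{load} loaded")
            ax.set_ylabel(label)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
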