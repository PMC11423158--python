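"""Basic plots: dose-response curves and crosstalk heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .circuit import CrosstalkMatrix
from .response import DoseResponseCurve


def plot_dose_response(curve: DoseResponseCurve, path: str | Path,
                       label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    conc = np.asarray(curve.concentrations, dtype=float)
    positive = conc > 0
    ax.semilogx(conc[positive], np.asarray(curve.responses)[positive],
                "o-", label=label or None)
    ax.axvline(curve.ec50, color="grey", ls="--", lw=0.8,
               label=f"EC50 = {curve.ec50:.2e} M")
    ax.set_xlabel("ligand concentration (M)")
    ax.set_ylabel("predicted output (a.u.)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_crosstalk(matrix: CrosstalkMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.0, 3.6))
    im = ax.imshow(matrix.values, cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(matrix.cols)), matrix.cols, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.rows)), matrix.rows)
    ax.set_xlabel("switch")
    ax.set_ylabel("trigger")
    fig.colorbar(im, ax=ax, label="relative activation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
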