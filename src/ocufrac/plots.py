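"""Simple line plots of the sweep results (ERR vs shape angle)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .protocols import SweepResult

__all__ = ["plot_sweep"]


def plot_sweep(sweep: SweepResult, path, xlabel: str = "angle [deg]",
               G_c: float | None = 5400.0) -> Path:
    df = sweep.frame().sort_values("angle")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["angle"], df["G"] / 1e3, "o-", ms=3, lw=1)
    if G_c is not None:
        ax.axhline(G_c / 1e3, color="r", ls="--", lw=1, label=r"$G_c$")
        ax.legend()
    ax.set_xlabel(xlabel)
    ax.set_ylabel(r"G [kJ/m$^2$]")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
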