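"""Figure-style output: event-aligned group mean-Z trajectories.

One panel per variable: x is the event-aligned day (-15..+13, where -15 is
the stable-period mean and 0 the day treatment started), y is the group mean
Z score, with horizontal lines at the detection threshold.  Each figure is
also backed by ``trajectories.csv`` so it can be regenerated.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import CAT, COMPOSITE, HR, PEF, SPO2  # noqa: E402

_PANELS = (CAT, PEF, HR, SPO2, COMPOSITE)


def plot_trajectories(analysis, outdir, threshold: float = 1.96) -> list[Path]:
    """Write one PNG per variable with per-arm mean-Z trajectories."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arms = sorted({p.arm for p in analysis.event_patients})
    paths = []
    for variable in _PANELS:
        fig, ax = plt.subplots(figsize=(7, 4))
        for arm in arms:
            traj = analysis.trajectory(variable, arm=arm)
            if traj.empty:
                continue
            ax.plot(traj.index, traj.values, marker="o", ms=3, label=arm)
        ax.axhline(threshold, color="red", lw=1)
        ax.axhline(-threshold, color="red", lw=1)
        ax.axvline(0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("day relative to treatment start (day -15 = stable mean)")
        ax.set_ylabel("group mean Z score")
        ax.set_title(variable)
        ax.legend()
        fig.tight_layout()
        path = outdir / f"trajectory_{variable}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
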