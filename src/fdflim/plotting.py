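"""Preview figures (phasor plot with universal semicircle and fitted chord).

Display-only: intensity previews use per-image max scaling, which is never
applied to analysis values.  matplotlib is imported lazily so the analysis
pipeline has no hard plotting dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .phasor import ChordFit, PhasorCloud


def plot_phasor(
    cloud: PhasorCloud,
    chord: ChordFit | None = None,
    out_path: str | Path | None = None,
    title: str = "",
):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "r-", lw=1,
            label="universal semicircle")
    ax.plot(cloud.g, cloud.s, ".", ms=1, alpha=0.3, label=f"{cloud.channel} phasors")
    if chord is not None and chord.intersects_circle and not chord.ill_conditioned:
        (g1, s1), (g2, s2) = chord.intersections
        ax.plot([g1, g2], [s1, s2], "k--", lw=1, label="TLS chord")
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 0.65)
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def plot_intensity_preview(dc: np.ndarray, out_path: str | Path):
    """Per-image max-normalized intensity preview (display only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    norm = dc / max(float(dc.max()), 1e-12)
    fig, ax = plt.subplots()
    ax.imshow(norm, cmap="gray", vmin=0, vmax=1)
    ax.set_axis_off()
    fig.savefig(out_path, dpi=100, bbox_inches="tight")
    plt.close(fig)
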