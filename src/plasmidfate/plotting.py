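"""Simple regeneration plots for sweep and basin results.

Colour conventions follow the field's habit for these diagrams: orange for
chromosomal resistance, blue for plasmid-borne, purple where both are stable,
white where neither is.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_REGIME_COLORS = {
    "no_resistance": "#ffffff",
    "chromosomal_only": "#e08214",
    "plasmid_only": "#4393c3",
    "bistable": "#762a83",
    "error": "#999999",
}

_OUTCOME_COLORS = {
    "plasmid_borne": "#4393c3",
    "chromosomal": "#e08214",
    "sensitive": "#f7f7f7",
    "extinct": "#f7f7f7",
    "mixed": "#1a9850",
    "error": "#999999",
}


def _grid_image(df: pd.DataFrame, xcol: str, ycol: str, vcol: str,
                colors: dict[str, str]) -> tuple[np.ndarray, list, list]:
    from matplotlib.colors import to_rgb
    xs = np.sort(df[xcol].unique())
    ys = np.sort(df[ycol].unique())
    img = np.ones((len(ys), len(xs), 3))
    lookup = {(round(r[xcol], 12), round(r[ycol], 12)): r[vcol]
              for _, r in df.iterrows()}
    for j, x in enumerate(xs):
        for i, y in enumerate(ys):
            val = lookup.get((round(x, 12), round(y, 12)))
            img[i, j] = to_rgb(colors.get(val, "#999999"))
    return img, xs, ys


def plot_grid(df: pd.DataFrame, xcol: str, ycol: str, vcol: str,
              out: str | Path, kind: str = "regime") -> Path:
    """Render a phase-diagram / basin-map style grid to a PNG or SVG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = _REGIME_COLORS if kind == "regime" else _OUTCOME_COLORS
    img, xs, ys = _grid_image(df, xcol, ycol, vcol, colors)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.imshow(img, origin="lower", aspect="auto",
              extent=(xs.min(), xs.max(), ys.min(), ys.max()))
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
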