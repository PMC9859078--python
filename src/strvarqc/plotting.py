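"""Diagnostic scatter plots with the four benchmark bands.

One figure per variance parameter: the log10(variance) vs log10(Tc) scatter,
the fitted regression and its +z*SD upper band (red, solid/dotted), and the
constant prior-gamma mode and 99th-percentile lines (black, solid/dotted).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .calibration import EmpiricalBand, predict
from .gamma_priors import PriorBenchmarks
from .report_io import InterpretationRecord, VarianceType, to_log_points

__all__ = ["plot_diagnostics"]

_TITLES = {
    VarianceType.ALLELE: "Allele variance",
    VarianceType.REVERSE_STUTTER: "Reverse stutter variance",
    VarianceType.FORWARD_STUTTER: "Forward stutter variance",
}


def plot_diagnostics(
    records: Sequence[InterpretationRecord],
    bands: Mapping[VarianceType, EmpiricalBand],
    priors: Mapping[VarianceType, PriorBenchmarks],
    out_dir: str | Path,
    fmt: str = "png",
) -> list[Path]:
    """Write one figure per parameter type; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for vt in VarianceType:
        band = bands[vt]
        prior = priors[vt]
        pts = to_log_points(records, vt)
        xs = np.array([p.x for p in pts])
        ys = np.array([p.y for p in pts])
        grid = np.linspace(*band.model.x_range, 200)
        mean = np.array([predict(band.model, g, warn_extrapolation=False) for g in grid])

        fig, ax = plt.subplots(figsize=(6, 4.2))
        ax.scatter(xs, ys, s=8, alpha=0.4, color="tab:blue", label="interpretations")
        ax.plot(grid, mean, color="red", label="regression")
        ax.plot(grid, mean + band.offset, color="red", linestyle=":", label=f"+{band.z} SD")
        if prior.log10_mode is not None:
            ax.axhline(prior.log10_mode, color="black", label="prior mode")
        ax.axhline(prior.log10_q99, color="black", linestyle=":", label="prior 99th pct")
        ax.set_xlabel("log10(Tc / RFU)")
        ax.set_ylabel("log10(variance parameter)")
        ax.set_title(_TITLES[vt])
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"{vt.value}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
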