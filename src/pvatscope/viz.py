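"""Slice-by-slice rendering of perivascular fat attenuation, and report
assembly.

Each axial slice containing fat voxels is exported as a static image: fat
HU shown with a perceptually uniform multi-hue colour-map on a colour scale
fixed to the fat window across all slices, a colour-bar, and the slice-mean
fat HU in the title.  A CSV index records per-slice mean and voxel count,
so regional attenuation heterogeneity can be read off without the images.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pvat_quant import FatWindow
from .volume_io import BinaryMask, ImageGrid, require_aligned

__all__ = ["render_fat_slices", "build_report"]

#: default perceptually uniform multi-hue ("rainbow") map
DEFAULT_CMAP = "turbo"


def render_fat_slices(
    grid: ImageGrid,
    fat: BinaryMask,
    out_dir: str | Path,
    window: FatWindow = FatWindow(),
    slice_axis: int = 2,
    cmap: str = DEFAULT_CMAP,
    write_images: bool = True,
) -> pd.DataFrame:
    """Render every fat-bearing slice and write the per-slice index CSV.

    Returns the index table with columns ``slice``, ``mean_hu``, ``n_fat``,
    ``vmin_hu``, ``vmax_hu`` (the colour-scale bounds, identical to the fat
    window in every row).  With no fat voxels anywhere, writes an empty CSV
    and warns instead of failing.
    """
    require_aligned(grid, fat)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    ks = np.unique(np.argwhere(fat.values)[:, slice_axis]) if fat.count() else []
    for k in ks:
        sl_fat = np.take(fat.values, k, axis=slice_axis)
        sl_hu = np.take(grid.values, k, axis=slice_axis)
        mean_hu = float(sl_hu[sl_fat].mean())
        records.append(
            {
                "slice": int(k),
                "mean_hu": mean_hu,
                "n_fat": int(sl_fat.sum()),
                "vmin_hu": window.lo_hu,
                "vmax_hu": window.hi_hu,
            }
        )
        if write_images:
            shown = np.where(sl_fat, sl_hu, np.nan)
            fig, ax = plt.subplots(figsize=(5, 5))
            im = ax.imshow(
                shown.T, origin="lower", cmap=cmap,
                vmin=window.lo_hu, vmax=window.hi_hu, interpolation="nearest",
            )
            ax.set_title(f"slice {k}: mean fat HU = {mean_hu:.1f}")
            ax.set_xlabel("x [vox]")
            ax.set_ylabel("y [vox]")
            fig.colorbar(im, ax=ax, label="HU")
            fig.savefig(out_dir / f"fat_slice_{int(k):04d}.png", dpi=100)
            plt.close(fig)
    index = pd.DataFrame(
        records, columns=["slice", "mean_hu", "n_fat", "vmin_hu", "vmax_hu"]
    )
    index.to_csv(out_dir / "fat_slices.csv", index=False)
    if index.empty:
        warnings.warn("no fat voxels anywhere: no slices rendered", stacklevel=2)
    return index


def _measurement_section(measurements) -> str:
    rows = [m.as_dict() if hasattr(m, "as_dict") else dict(m) for m in measurements]
    return pd.DataFrame(rows).to_markdown(index=False, floatfmt=".3f")


def _tests_section(tests) -> str:
    rows = [
        {
            "variable": t.variable, "method": t.method,
            "group 1 (residual)": t.summary_pos, "group 2 (closed)": t.summary_neg,
            "P": f"{t.p_value:.3g}" if np.isfinite(t.p_value) else "n/a",
        }
        for t in tests
    ]
    return pd.DataFrame(rows).to_markdown(index=False)


def _fits_section(fits) -> str:
    parts = []
    uni, multi = fits if isinstance(fits, tuple) else (fits, None)
    if uni:
        rows = [
            {
                "variable": f.variable,
                "95% CI": f"({f.ci_low:.3f}, {f.ci_high:.3f})" if f.converged else "—",
                "P": f"{f.p_value:.3g}" if f.converged else f.note,
            }
            for f in uni
        ]
        parts.append("**Univariate screen**\n\n" + pd.DataFrame(rows).to_markdown(index=False))
    if multi is not None:
        parts.append("**Multivariate model**\n\n" + multi.table().to_markdown(floatfmt=".3f"))
    return "\n\n".join(parts)


def _roc_section(rocs: dict) -> str:
    rows = [
        {
            "marker": name,
            "direction": r.direction,
            "AUC": f"{r.auc:.3f}",
            "Youden cut-off": f"{r.youden_cutoff:.3f}",
            "sensitivity": f"{r.youden_sensitivity:.3f}",
            "specificity": f"{r.youden_specificity:.3f}",
        }
        for name, r in rocs.items()
    ]
    return pd.DataFrame(rows).to_markdown(index=False)


def build_report(
    out_path: str | Path,
    measurements=None,
    tests=None,
    fits=None,
    rocs=None,
    provenance: dict | None = None,
) -> str:
    """Assemble the Markdown report; absent stages are marked, not fatal.

    Returns the report body (deterministic for identical inputs — no
    timestamps), and writes it to ``out_path``.
    """
    sections = [
        ("PVAT measurements", measurements, _measurement_section),
        ("Group comparisons", tests, _tests_section),
        ("Logistic modelling", fits, _fits_section),
        ("ROC analysis", rocs, _roc_section),
    ]
    lines = ["# PVAT attenuation analysis report", ""]
    for title, payload, fmt in sections:
        lines.append(f"## {title}")
        lines.append("")
        if payload is None or (hasattr(payload, "__len__") and len(payload) == 0):
            lines.append("_section absent: stage output not provided_")
        else:
            lines.append(fmt(payload))
        lines.append("")
    if provenance:
        lines.append("## Provenance")
        lines.append("")
        for k in sorted(provenance):
            lines.append(f"- {k}: {provenance[k]}")
        lines.append("")
    body = "\n".join(lines)
    Path(out_path).write_text(body)
    return body
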