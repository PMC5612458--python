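"""Static HTML/SVG visual reports.

Two report types mirror the screening workflow: a *group* report with one
strip/box panel per quality metric (points colored by site, each point
carrying the subject identifier and a hyperlink to its individual
report), and an *individual* report with orthogonal mosaic views,
segmentation contours and the image's full metric table.
"""
from __future__ import annotations

import html
import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError
from .iqms import IQM_NAMES

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
 body {{ font-family: sans-serif; margin: 2em; }}
 .panel {{ display: inline-block; margin: 4px; }}
 table {{ border-collapse: collapse; }}
 td, th {{ border: 1px solid #999; padding: 2px 8px; font-size: 90%; }}
</style></head>
<body><h1>{title}</h1>
{body}
</body></html>
"""


def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg")
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg") :]


def group_report(
    group_table: pd.DataFrame,
    out_html,
    iqm_columns: list[str] | None = None,
    link_pattern: str = "{subject_id}.html",
) -> Path:
    """Write the group report: one strip+box panel per IQM column.

    Each point is drawn with the subject identifier as its SVG id and a
    hyperlink following ``link_pattern``, so clicking a sample in a
    browser opens that subject's individual report.
    """
    if "subject_id" not in group_table.columns:
        raise ValidationError("group table lacks 'subject_id'")
    if iqm_columns is None:
        iqm_columns = [c for c in IQM_NAMES if c in group_table.columns]
    missing = [c for c in iqm_columns if c not in group_table.columns]
    if missing:
        raise ValidationError(f"group table lacks IQM columns: {missing}")
    if not iqm_columns:
        raise ValidationError("no IQM columns to plot")
    sites = (
        group_table["site"].astype(str)
        if "site" in group_table.columns
        else pd.Series(["all"] * len(group_table))
    )
    palette = plt.get_cmap("tab10")
    site_color = {s: palette(i % 10) for i, s in enumerate(sorted(sites.unique()))}
    rng = np.random.default_rng(0)
    panels = []
    for col in iqm_columns:
        vals = group_table[col].to_numpy(dtype=float)
        fig, ax = plt.subplots(figsize=(2.6, 2.4))
        finite = np.isfinite(vals)
        if finite.any():
            ax.boxplot(vals[finite], positions=[0], widths=0.5,
                       showfliers=False)
        jitter = rng.uniform(-0.15, 0.15, size=len(vals))
        pts = ax.scatter(
            jitter, vals,
            c=[site_color[s] for s in sites], s=12, alpha=0.8, zorder=3,
        )
        pts.set_urls(
            [link_pattern.format(subject_id=s) for s in group_table["subject_id"]]
        )
        pts.set_gid("samples-" + col)
        ax.set_title(col, fontsize=8)
        ax.set_xticks([])
        fig.tight_layout()
        panels.append(f'<span class="panel">{_fig_to_svg(fig)}</span>')
    out_html = Path(out_html)
    out_html.write_text(
        _PAGE.format(title="Group quality report", body="\n".join(panels))
    )
    return out_html


def _mosaic(ax_row, data, maps, axis: int, n_slices: int) -> None:
    n = data.shape[axis]
    picks = np.linspace(n * 0.2, n * 0.8, n_slices).astype(int)
    for ax, s in zip(ax_row, picks):
        sl = [slice(None)] * 3
        sl[axis] = s
        ax.imshow(data[tuple(sl)].T, cmap="gray", origin="lower")
        if maps is not None:
            for m, color in zip(maps, ("tab:blue", "tab:green", "tab:red")):
                plane = m[tuple(sl)].T
                if plane.max() > 0.5:
                    ax.contour(plane, levels=[0.5], colors=[color], linewidths=0.6)
        ax.set_axis_off()


def individual_report(
    vol,
    masks,
    tissues,
    iqm_vector: dict[str, float],
    out_html,
    n_slices: int = 5,
) -> Path:
    """Write one subject's report: axial/coronal/sagittal mosaics with
    tissue contours plus the full named metric table."""
    data = vol.data
    maps = [tissues.p_csf, tissues.p_gm, tissues.p_wm] if tissues is not None else None
    fig, axes = plt.subplots(3, n_slices, figsize=(1.8 * n_slices, 5.6))
    for axis in range(3):
        _mosaic(axes[axis], data, maps, axis, n_slices)
    fig.tight_layout()
    svg = _fig_to_svg(fig)
    rows = "\n".join(
        f"<tr><td>{html.escape(k)}</td><td>{v:.6g}</td></tr>"
        for k, v in iqm_vector.items()
    )
    body = (
        svg
        + f"<h2>Image quality metrics ({len(iqm_vector)})</h2>"
        + f"<table><tr><th>metric</th><th>value</th></tr>{rows}</table>"
    )
    out_html = Path(out_html)
    out_html.write_text(_PAGE.format(title="Individual quality report", body=body))
    return out_html
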