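"""Self-contained HTML QC report with one static plot per step."""

from __future__ import annotations

import base64
import html
import io
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

#: expected (k0, k1) positions for each relationship class
IBD_EXPECTED = {"DU": (0.0, 0.0), "PO": (0.0, 1.0),
                "FS": (0.25, 0.5), "HF": (0.5, 0.5), "UN": (1.0, 0.0)}

_POP_COLORS = {"AFR": "tab:orange", "EAS": "tab:green", "EUR": "tab:blue",
               "SAS": "tab:purple", "ASN": "tab:olive",
               "unknown": "tab:gray"}


def _fig_to_b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _plot_missing(result, config=None):
    df = result.metrics
    fig, ax = plt.subplots(figsize=(7, 3.2))
    if len(df):
        study = df["cohort"] == "study"
        x = np.arange(len(df))
        ax.scatter(x[study.values], df.loc[study, "missing_rate"], s=12,
                   color="tab:blue", label="study")
        ax.scatter(x[~study.values], df.loc[~study, "missing_rate"], s=12,
                   color="tab:gray", label="benchmark")
    thr = result.thresholds.get("missing_threshold", 0.1)
    ax.axhline(thr, color="red", ls="--", lw=1)
    ax.set_xlabel("sample index")
    ax.set_ylabel("missing rate")
    ax.legend(loc="upper right", fontsize=8)
    return fig


def _plot_sex(result, config=None):
    df = result.metrics
    fig, ax = plt.subplots(figsize=(7, 3.2))
    markers = {"female": "^", "male": "o", "unknown": "s"}
    for gender, mk in markers.items():
        sub = df[df["reported_gender"] == gender]
        if len(sub):
            flagged = sub["sample_id"].isin(
                [s for s, _ in result.flagged])
            ax.scatter(np.nonzero(df["reported_gender"].values
                                  == gender)[0],
                       sub["f_x"], marker=mk, s=18,
                       c=np.where(flagged, "red", "tab:cyan"),
                       label=f"reported {gender}")
    for key in ("sex_f_female_max", "sex_f_male_min"):
        ax.axhline(result.thresholds.get(key, 0), color="gray",
                   ls="--", lw=1)
    ax.set_xlabel("sample index")
    ax.set_ylabel("X inbreeding coefficient")
    ax.legend(loc="center right", fontsize=8)
    return fig


def _plot_inbreeding(result, config=None):
    df = result.metrics
    fig, ax = plt.subplots(figsize=(7, 3.2))
    if len(df):
        flagged = df["sample_id"].isin([s for s, _ in result.flagged])
        ax.scatter(np.arange(len(df)), df["f_autosomal"], s=14,
                   c=np.where(flagged, "red", "tab:blue"))
    mean = result.thresholds.get("mean", 0.0)
    sd = result.thresholds.get("sd", 0.0)
    mult = result.thresholds.get("inbreeding_sd_multiplier", 5.0)
    for y in (mean - mult * sd, mean + mult * sd):
        ax.axhline(y, color="gray", ls="--", lw=1)
    ax.set_xlabel("sample index")
    ax.set_ylabel("autosomal inbreeding coefficient")
    return fig


def _plot_ibd(result, config=None):
    df = result.metrics
    fig, ax = plt.subplots(figsize=(5.2, 4.6))
    colors = {"DU": "red", "PO": "pink", "FS": "green", "HF": "orange",
              "UN": "black"}
    pred = df["predicted"].values if len(df) else np.array([])
    for rel, color in colors.items():
        sub = df[pred == rel] if len(df) else df
        if len(sub):
            ax.scatter(sub["k0"], sub["k1"], s=8, color=color, label=rel,
                       alpha=0.6 if rel == "UN" else 1.0)
    for rel, (k0, k1) in IBD_EXPECTED.items():
        ax.plot(k0, k1, "+", color="gray", ms=12, mew=2)
        ax.annotate(rel, (k0, k1), textcoords="offset points",
                    xytext=(5, 5), fontsize=8, color="gray")
    ax.set_xlabel("k0")
    ax.set_ylabel("k1")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    ax.legend(loc="upper right", fontsize=8)
    return fig


def _plot_population(result, config=None):
    df = result.metrics
    fig, ax = plt.subplots(figsize=(5.2, 4.6))
    if "ev1" in df.columns and "ev2" in df.columns:
        for pop in sorted(df["reported_population"].unique()):
            sub = df[df["reported_population"] == pop]
            bench = sub["cohort"] == "benchmark"
            color = _POP_COLORS.get(pop, "tab:gray")
            if bench.any():
                ax.scatter(sub.loc[bench, "ev1"], sub.loc[bench, "ev2"],
                           s=14, color=color, marker="o",
                           label=f"{pop} (benchmark)")
            if (~bench).any():
                ax.scatter(sub.loc[~bench, "ev1"], sub.loc[~bench, "ev2"],
                           s=14, color=color, marker="x",
                           label=f"{pop} (study)")
        flagged_ids = {s for s, _ in result.flagged}
        fl = df["sample_id"].isin(flagged_ids)
        if fl.any():
            ax.scatter(df.loc[fl, "ev1"], df.loc[fl, "ev2"], s=70,
                       facecolors="none", edgecolors="red",
                       label="flagged")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(loc="best", fontsize=7)
    return fig


_PLOTTERS = {"missing": _plot_missing, "sex": _plot_sex,
             "inbreeding": _plot_inbreeding, "ibd": _plot_ibd,
             "population": _plot_population}

_TITLES = {"missing": "Sample missing rate check",
           "sex": "Sex check (X inbreeding coefficient)",
           "inbreeding": "Inbreeding check",
           "ibd": "IBD / relatedness check",
           "population": "Population outlier check"}


def render_report(results, config, out_path) -> Path:
    """Render all step results into one self-contained HTML file."""
    out_path = Path(out_path)
    sections = []
    total_flagged = 0
    for result in results:
        total_flagged += len(result.flagged)
        img = _fig_to_b64(_PLOTTERS[result.step](result, config))
        rows = "".join(
            f"<tr><td>{html.escape(sid)}</td>"
            f"<td>{html.escape(reason)}</td></tr>"
            for sid, reason in result.flagged)
        flag_table = (
            "<table><tr><th>sample</th><th>reason</th></tr>"
            f"{rows}</table>" if result.flagged
            else "<p>No problematic samples at this step.</p>")
        warns = "".join(f"<p class='warn'>Warning: {html.escape(w)}</p>"
                        for w in result.warnings)
        sections.append(
            f"<section id='step-{result.step}'>"
            f"<h2>{_TITLES[result.step]}</h2>{warns}"
            f"<img src='data:image/png;base64,{img}' "
            f"alt='{result.step} plot'/>"
            f"{flag_table}</section>")

    cfg_rows = "".join(
        f"<tr><td>{html.escape(str(k))}</td>"
        f"<td>{html.escape(str(v))}</td></tr>"
        for k, v in config.to_dict().items())
    summary = (f"<p><b>{total_flagged}</b> problematic sample(s) "
               "identified." if total_flagged
               else "<p>No problematic samples identified.")
    page = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Sample QC report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 60em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 2px 8px; font-size: 90%; }}
.warn {{ color: #a60; }}
img {{ max-width: 100%; }}
</style></head><body>
<h1>Sample QC report</h1>
{summary}</p>
{''.join(sections)}
<section><h2>Configuration</h2>
<table><tr><th>option</th><th>value</th></tr>{cfg_rows}</table></section>
</body></html>
"""
    out_path.write_text(page)
    return out_path
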