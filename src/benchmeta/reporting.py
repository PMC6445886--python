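"""Report assembly and publication-style plots.

``build_report`` serializes any combination of analysis results into a
deterministic JSON-ready dictionary (stable key order, provenance block
with seed/config hash/version); the plotting helpers draw the standard
meta-analytic figures. Plots are artifacts: every number shown is
traceable to a report field, and downstream checks read the JSON, never
the images.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any, Dict, Optional

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from . import __version__
from .datatypes import PooledEstimate

__all__ = ["build_report", "report_to_json", "forest_plot", "funnel_plot",
           "baujat_plot", "weighted_histogram_plot", "metareg_plot"]


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if callable(obj):
        return None  # functions (e.g. CI contours) are not serializable
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    return obj


def build_report(seed: Optional[int] = None, config: Optional[dict] = None,
                 **sections: Any) -> Dict[str, Any]:
    """Assemble a deterministic report from analysis outputs.

    Any keyword section (``pooled=``, ``heterogeneity=``,
    ``sensitivity=`` ...) is serialized; at least one must be given.
    Sections carrying a ``scale`` attribute must agree on it.
    """
    if not sections:
        raise ValueError("at least one result section is required")
    scales = set()
    for v in sections.values():
        items = v if isinstance(v, (list, tuple)) else [v]
        for item in items:
            s = getattr(item, "scale", None)
            if s is not None:
                scales.add(s)
    if len(scales) > 1:
        raise ValueError(f"conflicting scales across inputs: {sorted(scales)}")

    cfg = config or {}
    cfg_hash = hashlib.sha256(
        json.dumps(_to_jsonable(cfg), sort_keys=True).encode()).hexdigest()[:16]
    report = {
        "provenance": {
            "tool": "benchmeta",
            "version": __version__,
            "seed": seed,
            "config": _to_jsonable(cfg),
            "config_hash": cfg_hash,
        },
    }
    if scales:
        report["scale"] = scales.pop()
    for name in sorted(sections):
        report[name] = _to_jsonable(sections[name])
    return report


def report_to_json(report: Dict[str, Any]) -> str:
    """Byte-stable serialization (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2)


def _new_axes(figsize=(6.4, 4.8)):
    fig = Figure(figsize=figsize)
    FigureCanvasAgg(fig)
    return fig, fig.add_subplot(111)


def _save(fig: Figure, path) -> None:
    fig.savefig(path, bbox_inches="tight")


def forest_plot(effects, pooled: PooledEstimate, path, alpha: float = 0.05) -> None:
    """Study-level estimates with CIs and the pooled estimate band."""
    from .pooling import critical_value

    fig, ax = _new_axes((6.4, max(3.0, 0.3 * len(effects) + 1.5)))
    v = critical_value(alpha, len(effects), "z")
    for i, e in enumerate(effects):
        ax.errorbar(e.theta, i, xerr=v * e.se, fmt="ko", ms=4, capsize=2)
    ax.axvspan(pooled.ci[0], pooled.ci[1], color="tab:red", alpha=0.2)
    ax.axvline(pooled.theta_hat, color="tab:red")
    ax.set_yticks(range(len(effects)))
    ax.set_yticklabels([e.study_id for e in effects], fontsize=7)
    ax.set_xlabel("effect size")
    _save(fig, path)


def funnel_plot(funnel_data, path) -> None:
    """Effect vs precision with the expected no-bias contour."""
    fig, ax = _new_axes()
    ax.plot(funnel_data.theta, funnel_data.precision, "ko", ms=4)
    prec = np.linspace(funnel_data.precision.min(), funnel_data.precision.max(), 100)
    lo = [funnel_data.ci_bounds(1.0 / p)[0] for p in prec]
    hi = [funnel_data.ci_bounds(1.0 / p)[1] for p in prec]
    ax.plot(lo, prec, "gray", hi, prec, "gray", lw=0.8)
    ax.axvline(funnel_data.fixed_line, color="tab:blue", ls="--", label="fixed")
    ax.axvline(funnel_data.random_line, color="tab:red", ls="--", label="random")
    ax.set_xlabel("effect size")
    ax.set_ylabel("precision (1/se)")
    ax.legend()
    _save(fig, path)


def baujat_plot(points, path) -> None:
    """Heterogeneity contribution vs influence on the pooled effect."""
    fig, ax = _new_axes()
    ax.plot([p.x for p in points], [p.y for p in points], "ko", ms=4)
    for p in points:
        ax.annotate(p.study_id, (p.x, p.y), fontsize=6,
                    textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel("contribution to heterogeneity")
    ax.set_ylabel("influence on pooled effect")
    _save(fig, path)


def weighted_histogram_plot(hist, path) -> None:
    fig, ax = _new_axes()
    widths = np.diff(hist.bin_edges)
    ax.bar(hist.bin_edges[:-1], hist.P, width=widths, align="edge",
           color="gray", edgecolor="black")
    ax.set_xlabel("effect size")
    ax.set_ylabel("weighted frequency")
    _save(fig, path)


def metareg_plot(effects, x, result, path) -> None:
    """Scatter (marker area ~ weight) with the fitted regression band."""
    fig, ax = _new_axes()
    theta = np.array([e.theta for e in effects])
    se = np.array([e.se for e in effects])
    w = 1.0 / (se ** 2 + result.tau2_residual)
    x = np.asarray(x, dtype=float)
    ax.scatter(x, theta, s=40 * w / w.max(), c="k")
    xs = np.linspace(x.min(), x.max(), 50)
    b0, b1 = result.beta[0], result.beta[1]
    ax.plot(xs, b0 + b1 * xs, "tab:red")
    lo = [result.ci_beta[0][0] + result.ci_beta[1][0] * v for v in xs]
    hi = [result.ci_beta[0][1] + result.ci_beta[1][1] * v for v in xs]
    ax.fill_between(xs, lo, hi, color="tab:red", alpha=0.15)
    ax.set_xlabel("covariate")
    ax.set_ylabel("effect size")
    _save(fig, path)
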