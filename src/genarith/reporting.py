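"""Report rendering: JSON/CSV/text prediction reports and the comparison table."""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .genotype_arithmetic import PredictionReport, predict_binding_sites
from .powerlaw_cascade import (build_end_product_cascade, classify_eigenvalues,
                               jacobian, linearize_and_classify,
                               solve_steady_state)

__all__ = [
    "write_report_files",
    "render_text_report",
    "comparison_table",
    "stability_boundary",
    "trajectory_frame",
]


def render_text_report(report: PredictionReport) -> str:
    """Human-readable report mirroring the per-cone pipeline columns
    (equation -> cone -> sampled matrix -> Hilbert basis -> constraints).
    Row labels are printed 1-based."""
    out = []
    out.append(f"Genotype-arithmetic prediction, pathway length n = {report.n}")
    out.append(f"divisor = {report.divisor} "
               f"({report.n} species cones + {report.divisor - report.n} constraint cone)")
    r = report.g_range
    lo = "-inf" if r.lower is None else str(r.lower)
    hi = "+inf" if r.upper is None else str(r.upper)
    out.append(f"g range (intersect): [{lo}, {hi}]"
               + ("  (candidates truncated)" if r.truncated else ""))
    rs = report.g_range_summed
    lo, hi = ("-inf" if rs.lower is None else str(rs.lower),
              "+inf" if rs.upper is None else str(rs.upper))
    out.append(f"g range (summed):    [{lo}, {hi}]")
    out.append("integer candidates: " + ", ".join(map(str, r.integer_candidates)))
    out.append("stability: " + ", ".join(
        f"g={g}:{c}" for g, c in sorted(report.stability_at_candidates.items())))
    out.append(f"max-projection rows (1-based, at g={report.projection_g}): "
               + ", ".join(str(i + 1) for i in report.max_projection_rows))
    out.append("")
    out.append("bistochastic aggregate (rows/cols sum to 1):")
    for row in report.bistochastic.values:
        out.append("  " + "  ".join(f"{str(x):>5}" for x in row))
    for a in report.artifacts:
        out.append("")
        out.append(f"-- cone {a.label} --")
        out.append("  lattice-cone rows:")
        for rr in a.cone_rows:
            out.append("    " + " ".join(f"{x:>3}" for x in rr))
        out.append("  sampled dual matrix:")
        for rr in a.dual_matrix:
            out.append("    " + " ".join(f"{x:>3}" for x in rr))
        out.append("  Hilbert basis:")
        for e in a.basis.elements:
            out.append("    " + " ".join(f"{x:>3}" for x in e))
        out.append("  permuted identity:")
        for rr in a.permutation:
            out.append("    " + " ".join(f"{x:>3}" for x in rr))
    out.append("")
    return "\n".join(out)


def write_report_files(report: PredictionReport, outdir) -> Dict[str, Path]:
    """Write report.json, bistochastic.csv and report.txt; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n")
    paths["json"] = jpath
    cpath = outdir / "bistochastic.csv"
    size = report.bistochastic.size
    df = pd.DataFrame(report.bistochastic.as_float(),
                      columns=[f"c{j+1}" for j in range(size)])
    df.to_csv(cpath, index=False)
    paths["csv"] = cpath
    tpath = outdir / "report.txt"
    tpath.write_text(render_text_report(report))
    paths["txt"] = tpath
    return paths


def stability_boundary(n: int, g_hi: float = 64.0, tol: float = 1e-6,
                       alpha=None, beta=None, h=None) -> float:
    """Numeric |g| where the cascade loses stability (bisection on the sweep)."""
    def stable(g: float) -> bool:
        model = build_end_product_cascade(n, g=Fraction(g).limit_denominator(10**6),
                                          alpha=alpha, beta=beta, h=h)
        ss = solve_steady_state(model, Fraction(g).limit_denominator(10**6))
        eigs = np.linalg.eigvals(jacobian(model, ss.concentrations,
                                          Fraction(g).limit_denominator(10**6)))
        return classify_eigenvalues(eigs) == "stable"

    lo, hi = 0.0, float(g_hi)
    if stable(hi):
        return float("inf")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stable(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def comparison_table(lengths: Sequence[int] = range(3, 10),
                     classic: Optional[Dict[int, float]] = None,
                     configs: Optional[Dict[int, RunConfig]] = None,
                     boundary: bool = True) -> pd.DataFrame:
    """Comparison of classic-analysis g values against the predicted ranges.

    ``classic`` supplies the reference values (they are reported only
    graphically in the source analysis, so they are user-provided); missing
    entries render as "n/a".  Optionally adds the numerically computed
    stability boundary per length.
    """
    rows = []
    for n in lengths:
        cfg = (configs or {}).get(n) or RunConfig(n=n)
        rep = predict_binding_sites(n, cfg)
        r = rep.g_range
        lo = "-inf" if r.lower is None else str(r.lower)
        hi = "+inf" if r.upper is None else str(r.upper)
        stable = [g for g, c in sorted(rep.stability_at_candidates.items())
                  if c == "stable"]
        row = {
            "n": n,
            "classic_g": (classic or {}).get(n, "n/a"),
            "predicted_range": f"[{lo}, {hi}]",
            "stable_candidates": ",".join(map(str, stable)),
            "divisor": rep.divisor,
        }
        if boundary:
            row["stability_boundary"] = round(stability_boundary(n), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def trajectory_frame(t: np.ndarray, X: np.ndarray) -> pd.DataFrame:
    """Trajectory matrix as a t,X1..Xn data frame (the CSV layout)."""
    n = X.shape[1]
    df = pd.DataFrame(X, columns=[f"X{i+1}" for i in range(n)])
    df.insert(0, "t", t)
    return df
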