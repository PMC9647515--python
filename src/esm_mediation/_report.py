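"""Fixed-width, publication-shaped text rendering of result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def format_p(p: float) -> str:
    """p-values below 0.0005 are rendered '<0.001'."""
    if p is None or not np.isfinite(p):
        return "n/a"
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


def _num(x, nd: int = 3) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "n/a"
    return f"{x:.{nd}f}"


def render_mediation_table(results) -> str:
    """Total, direct and conditional indirect effects with contrasts.

    Proportions mediated exceeding 1 under suppression keep their value
    and receive a footnote marker.
    """
    direction = {
        "x2y": "stress -> negative affect -> psychotic experiences",
        "y2x": "psychotic experiences -> negative affect -> stress",
    }[results.direction]
    lines = [
        f"Cross-sectional moderated mediation: {direction}",
        "",
        f"{'':22s}{'Total':>10s}{'Direct':>10s}{'Indirect':>10s}"
        f"{'95% CI':>20s}{'P_M':>9s}",
    ]
    suppressed = False
    for rec in results.table().to_dict(orient="records"):
        ci = f"({_num(rec['ci_lower'])} to {_num(rec['ci_upper'])})"
        pm = _num(rec["prop_mediated"], 2)
        if rec["suppression"]:
            pm += "c"
            suppressed = True
        lines.append(
            f"{rec['row']:<22s}{_num(rec['total']):>10s}"
            f"{_num(rec['direct']):>10s}{_num(rec['indirect']):>10s}"
            f"{ci:>20s}{pm:>9s}"
        )
    lines.append("")
    lines.append("All models adjusted for age and gender.")
    if suppressed:
        lines.append(
            "c Exceeds 1.0: direct effect opposite in sign to the indirect "
            "effect (suppression)."
        )
    return "\n".join(lines)


def render_ar_table(res) -> str:
    """Autoregressive (t-1 -> t) effects per measure and group."""
    lines = [
        "Autoregressive effects (t-1 -> t)",
        "",
        f"{'measure':<24s}{'group':<10s}{'B':>8s}{'s.e.':>8s}{'p':>8s}",
    ]
    for rec in res.ar_table().to_dict(orient="records"):
        lines.append(
            f"{rec['measure']:<24s}{rec['group']:<10s}"
            f"{_num(rec['estimate']):>8s}{_num(rec['se']):>8s}"
            f"{format_p(rec['p']):>8s}"
        )
    return "\n".join(lines)


def render_clpm_table(res) -> str:
    """Lagged total/direct/indirect effects per direction and group."""
    titles = {
        "forward": "stress(t-1) -> negative affect -> psychotic experiences(t)",
        "reverse": "psychotic experiences(t-1) -> negative affect -> stress(t)",
    }
    lines = [f"Cross-lagged panel mediation ({res.variant} model)"]
    for direction, rows in res.indirect.items():
        lines += [
            "",
            titles[direction],
            f"{'':22s}{'Total':>10s}{'Direct':>10s}{'Indirect':>10s}{'95% CI':>22s}",
        ]
        tab = res.table()
        sub = tab[tab["direction"] == direction]
        for rec in sub.to_dict(orient="records"):
            ci = f"({_num(rec['ci_lower'])} to {_num(rec['ci_upper'])})"
            lines.append(
                f"{rec['row']:<22s}{_num(rec['total']):>10s}"
                f"{_num(rec['direct']):>10s}{_num(rec['indirect']):>10s}{ci:>22s}"
            )
    return "\n".join(lines)


def render_aggregates(agg) -> str:
    """Group-level aggregate ESM scores and pairwise comparisons."""
    lines = [
        "Aggregate ESM scores (person means)",
        "",
        f"{'group':<10s}{'n':>5s}"
        + "".join(f"{m:>22s}" for m in ("stress", "negative affect", "psychotic exp.")),
    ]
    for rec in agg.group_table.to_dict(orient="records"):
        cells = []
        for c in ("stress", "negative_affect", "psychotic_experiences"):
            cells.append(f"{_num(rec[c + '_mean'], 2)} ({_num(rec[c + '_sd'], 2)})")
        lines.append(
            f"{rec['group']:<10s}{rec['n']:>5d}" + "".join(f"{c:>22s}" for c in cells)
        )
    lines += ["", "Pairwise Welch comparisons of person means (95% CI):"]
    for rec in agg.comparisons.to_dict(orient="records"):
        lines.append(
            f"  {rec['comparison']:<22s}{rec['measure']:<24s}"
            f"{_num(rec['diff'], 2):>8s} "
            f"({_num(rec['ci_lower'], 2)} to {_num(rec['ci_upper'], 2)}), "
            f"p = {format_p(rec['p'])}"
        )
    return "\n".join(lines)


def render_fit_comparison(table: pd.DataFrame) -> str:
    lines = [
        "Model fit",
        "",
        f"{'variant':<16s}{'loglik':>12s}{'AIC':>12s}{'BIC':>12s}"
        f"{'dAIC':>10s}{'dBIC':>10s}",
    ]
    for rec in table.to_dict(orient="records"):
        lines.append(
            f"{rec['variant']:<16s}{_num(rec['loglik'], 1):>12s}"
            f"{_num(rec['aic'], 1):>12s}{_num(rec['bic'], 1):>12s}"
            f"{_num(rec['d_aic'], 1):>10s}{_num(rec['d_bic'], 1):>10s}"
        )
    return "\n".join(lines)
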