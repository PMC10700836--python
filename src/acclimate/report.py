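"""Publication-style text tables for fits, sweeps and projections."""

from __future__ import annotations

import pandas as pd

from .estimation import ModelFit

__all__ = ["stars", "render_tables", "coefficient_table", "sweep_table"]


def stars(p: float) -> str:
    """Significance stars at the 0.01 / 0.05 / 0.1 thresholds."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def coefficient_table(fits: dict[str, ModelFit], digits: int = 4) -> str:
    """Column-per-model coefficient table, clustered SEs in parentheses."""
    if not fits:
        return "(no fits)\n"
    rows: dict[str, dict[str, str]] = {}
    for name, fit in fits.items():
        for coef in fit.params.index:
            cell = (f"{fit.params[coef]:.{digits}f}{stars(float(fit.pvalues[coef]))}"
                    f" ({fit.se[coef]:.{digits}f})")
            rows.setdefault(coef, {})[name] = cell
    frame = pd.DataFrame(rows).T.reindex(columns=list(fits))
    meta = pd.DataFrame(
        {
            name: {
                "N": str(fit.n_obs),
                "clusters": "x".join(str(v) for v in fit.n_clusters.values()),
            }
            for name, fit in fits.items()
        }
    )
    out = pd.concat([frame, meta]).fillna("")
    legend = "Notes: clustered SEs in parentheses. ***p<0.01, **p<0.05, *p<0.1.\n"
    return out.to_string() + "\n" + legend


def sweep_table(sweep: pd.DataFrame, digits: int = 4) -> str:
    """Reference-construction sweep: coefficient, CI, years-missed share."""
    if sweep is None or len(sweep) == 0:
        return "(empty sweep)\n"
    cols = ["scheme", "param", "beta", "se", "ci_lower", "ci_upper",
            "mean_years_missed", "n_obs"]
    view = sweep[[c for c in cols if c in sweep.columns]].copy()
    for c in view.select_dtypes("float").columns:
        view[c] = view[c].round(digits)
    return view.to_string(index=False) + "\n"


def render_tables(fits: dict[str, ModelFit] | None = None,
                  sweeps: pd.DataFrame | None = None,
                  projections: pd.DataFrame | None = None) -> str:
    """Assemble the human-readable report for whatever outputs exist."""
    parts = []
    if fits:
        parts += ["== Coefficient estimates ==", coefficient_table(fits)]
    if sweeps is not None:
        parts += ["== Reference-construction sweep ==", sweep_table(sweeps)]
    if projections is not None:
        view = projections.copy()
        for c in view.select_dtypes("float").columns:
            view[c] = view[c].round(4)
        parts += ["== Projection summary ==", view.to_string(index=False) + "\n"]
    return "\n".join(parts) if parts else "(nothing to report)\n"
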