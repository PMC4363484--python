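"""Human-readable reporting of the trait summary and fitted models."""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .inference import AveragedModel, ModelFit, PathResult

__all__ = ["render_report"]


def _fmt(df: pd.DataFrame, digits: int = 3) -> str:
    return df.round(digits).to_string()


def render_report(
    summary: pd.DataFrame,
    growth: AveragedModel,
    sa_model: ModelFit | None,
    path: PathResult | None,
    interactions: list[str] | None = None,
) -> str:
    """Format the analysis results as a plain-text report.

    Sections mirror the analysis: trait summary (mean/min/max/SD/CV), the
    averaged growth model (beta, adjusted SE, z, P, relative importance and
    its component models with delta-AIC and weight), the full sapwood-area
    model, and the saturated path model.
    """
    out = StringIO()
    w = out.write
    w("Canopy-tree biomass growth analysis\n")
    w("=" * 60 + "\n\n")

    w("Trait summary (per tree-level variable)\n")
    w("-" * 60 + "\n")
    s = summary.copy()
    s["cv"] = s["cv"].round(2)
    w(_fmt(s) + "\n\n")

    w("Growth model: averaged over models within "
      f"{growth.delta_cut:g} AIC units of the best\n")
    w("-" * 60 + "\n")
    if interactions is not None:
        w(f"retained species x trait interactions: {interactions or 'none'}\n")
    w(_fmt(growth.summary_frame()) + "\n\n")
    w("relative variable importance:\n")
    w(_fmt(growth.importance.to_frame("importance")) + "\n\n")
    best = growth.component_models[0].aic
    comp = pd.DataFrame([
        {"terms": " + ".join(t for t in f.terms) or "(intercept)",
         "aic": f.aic, "delta_aic": f.aic - best, "weight": wt}
        for f, wt in zip(growth.component_models, growth.weights)
    ])
    w("component models:\n" + _fmt(comp) + "\n\n")

    if sa_model is not None:
        w("Sapwood-area model (full model, observed SA only)\n")
        w("-" * 60 + "\n")
        sa_df = pd.DataFrame({"beta": sa_model.params, "se": sa_model.se,
                              "t": sa_model.tvalues, "p": sa_model.pvalues})
        w(_fmt(sa_df) + f"\nAIC = {sa_model.aic:.2f}, n = {sa_model.n}\n\n")

    if path is not None:
        w("Saturated path model (species-mean-centered variables)\n")
        w("-" * 60 + "\n")
        w("paths into growth:\n" + _fmt(path.paths) + "\n")
        w("predictor correlations:\n" + _fmt(path.correlations) + "\n")
        w(f"n = {path.n}\n")
    return out.getvalue()
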