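"""Parameter-recovery harnesses.

These run the full statistical pipeline on replicate synthetic trait tables
whose ground truth is the generator's published-effect structure, and report
how well the fitted models recover it.  Sapwood masking is disabled here:
the harness scores the estimator itself, not the imputation step (which is
scored separately by the imputation-accuracy tests).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .inference import (
    GROWTH_DESIGN,
    average_models,
    enumerate_subsets,
    fit_sa_model,
    transform_and_scale,
)
from .synthetic import GeneratorConfig, default_config, generate_trait_table

__all__ = ["RecoveryResult", "recover_growth_model", "recover_sa_model",
           "replicate_seeds"]


@dataclass
class RecoveryResult:
    """Per-replicate estimates for one coefficient plus the ground truth."""

    estimates: np.ndarray
    truth: float
    extra: pd.DataFrame  # per-replicate bookkeeping (importances etc.)

    @property
    def mean(self) -> float:
        return float(self.estimates.mean())

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the replicate mean."""
        return float(self.estimates.std(ddof=1) / np.sqrt(len(self.estimates)))


def replicate_seeds(seed: int, n_reps: int) -> list[int]:
    """Independent sub-seeds (< 2^31) for the replicate simulations."""
    ss = np.random.SeedSequence(seed).spawn(n_reps)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]


def _unmasked(cfg: GeneratorConfig | None) -> GeneratorConfig:
    cfg = cfg or default_config()
    return replace(cfg, mask_sa=False)


def recover_growth_model(
    cfg: GeneratorConfig | None = None,
    n_scale: int = 10,
    n_reps: int = 50,
    seed: int = 1,
    delta_cut: float = 2.0,
) -> RecoveryResult:
    """Recover the growth model's log(SA) coefficient by subset averaging.

    Each replicate simulates a trait table (species counts x ``n_scale``),
    standardizes, fits all predictor subsets with the species factor, and
    averages the models within ``delta_cut`` AIC units.  Returns the
    replicate estimates of the log(SA) coefficient, the generator truth, and
    per-replicate SA importance / selected-set size.
    """
    cfg = _unmasked(cfg)
    truth = dict(cfg.growth_coef)["sa"]
    est, rows = [], []
    for s in replicate_seeds(seed, n_reps):
        traits, _ = generate_trait_table(cfg, seed=s, n_scale=n_scale)
        dm = transform_and_scale(traits, GROWTH_DESIGN)
        avg = average_models(enumerate_subsets(dm), delta_cut=delta_cut)
        est.append(avg.coefficients.get("log(sa)", np.nan))
        rows.append({
            "seed": s,
            "sa_importance": avg.importance.get("log(sa)", 0.0),
            "species_importance": avg.importance.get("species", 0.0),
            "n_selected": len(avg.component_models),
        })
    return RecoveryResult(np.asarray(est), truth, pd.DataFrame(rows))


def recover_sa_model(
    cfg: GeneratorConfig | None = None,
    n_scale: int = 10,
    n_reps: int = 50,
    seed: int = 1,
) -> RecoveryResult:
    """Recover the SA model's sapwood-growth coefficient (full model)."""
    cfg = _unmasked(cfg)
    truth = dict(cfg.sa_coef)["sapwood_growth"]
    est, rows = [], []
    for s in replicate_seeds(seed, n_reps):
        traits, _ = generate_trait_table(cfg, seed=s, n_scale=n_scale)
        fit = fit_sa_model(traits)
        est.append(fit.params["sapwood_growth"])
        rows.append({
            "seed": s,
            "lifespan_coef": fit.params["sapwood_lifespan"],
            "ba_coef": fit.params["log(ba)"],
        })
    return RecoveryResult(np.asarray(est), truth, pd.DataFrame(rows))
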