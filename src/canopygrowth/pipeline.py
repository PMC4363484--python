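"""End-to-end orchestration: simulate -> derive -> fit -> report.

Every run writes its artifacts plus a manifest (subcommand, config hash,
seed, input digests, package version, timestamps) so results can be traced
back to their exact inputs.  Exit codes: 0 success, 2 validation failure,
3 inference failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data_model import read_field_tables, validate_tree, write_field_tables
from .errors import CanopyGrowthError, InferenceError
from .inference import (
    fit_growth_model,
    fit_sa_model,
    impute_missing_sa,
    path_analysis,
    summarize_traits,
)
from .reconstruction import derive_traits
from .report import render_report
from .synthetic import GeneratorConfig, default_config, generate_field_dataset

__all__ = ["RunManifest", "run_pipeline", "EXIT_OK", "EXIT_VALIDATION",
           "EXIT_INFERENCE"]

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_INFERENCE = 3


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    subcommand: str
    seed: int
    config_hash: str
    package_version: str = __version__
    started: str = ""
    finished: str = ""
    status: str = "running"
    failure_stage: str | None = None
    input_digests: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, outdir: Path) -> Path:
        p = outdir / "manifest.json"
        p.write_text(json.dumps(asdict(self), indent=2))
        return p


def run_pipeline(
    outdir: str | Path,
    seed: int,
    config: GeneratorConfig | None = None,
    input_dir: str | Path | None = None,
    n_scale: int = 1,
    impute_sa: bool = True,
    delta_cut: float = 2.0,
    use_aicc: bool = False,
) -> int:
    """Run simulate (or ingest CSVs from ``input_dir``), derive, fit, report.

    Writes the raw tables (when simulating), ``traits.csv``,
    ``derived_discs.csv``, ``model_report.txt``, machine-readable model
    tables and ``manifest.json`` into ``outdir``.  Returns an exit status;
    partial outputs are retained with the manifest marking the failed stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or default_config()
    cfg_digest = hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(subcommand="all", seed=seed, config_hash=cfg_digest,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    stage = "simulate"
    try:
        if input_dir is None:
            trees, _, _ = generate_field_dataset(cfg, seed=seed, n_scale=n_scale)
            paths = write_field_tables(trees, outdir / "raw")
            manifest.input_digests = {k: _sha256(p) for k, p in paths.items()}
            logger.info("simulated %d trees", len(trees))
            trees = read_field_tables(outdir / "raw")
        else:
            stage = "derive"
            input_dir = Path(input_dir)
            manifest.input_digests = {
                p.stem: _sha256(p) for p in sorted(input_dir.glob("*.csv"))}
            trees = read_field_tables(input_dir)
            logger.info("read %d trees from %s", len(trees), input_dir)

        stage = "validate"
        violations = [v for t in trees for v in validate_tree(t)]
        if violations:
            vdf = pd.DataFrame([v.__dict__ for v in violations])
            vdf.to_csv(outdir / "violations.csv", index=False)
            raise CanopyGrowthError(
                f"{len(violations)} validation violation(s); see violations.csv")

        stage = "derive"
        traits, discs = derive_traits(trees)
        traits.to_csv(outdir / "traits.csv", index=False)
        discs.to_csv(outdir / "derived_discs.csv", index=False)
        logger.info("derived traits for %d trees", len(traits))

        stage = "fit"
        summary = summarize_traits(traits)
        fit_table = impute_missing_sa(traits) if impute_sa \
            else traits[traits["sa"].notna()]
        growth, fits, interactions = fit_growth_model(
            fit_table, delta_cut=delta_cut, use_aicc=use_aicc)
        try:
            sa_model = fit_sa_model(traits)
        except InferenceError:
            sa_model = None
        path_res = path_analysis(fit_table)

        stage = "report"
        text = render_report(summary, growth, sa_model, path_res, interactions)
        (outdir / "model_report.txt").write_text(text)
        summary.to_csv(outdir / "trait_summary.csv")
        growth.summary_frame().assign(
            importance=lambda d: d.index.map(
                lambda c: growth.importance.get(c, pd.NA))
        ).to_csv(outdir / "growth_model.csv")
        if sa_model is not None:
            pd.DataFrame({"beta": sa_model.params, "se": sa_model.se,
                          "t": sa_model.tvalues, "p": sa_model.pvalues,
                          }).to_csv(outdir / "sa_model.csv")
        manifest.outputs = sorted(p.name for p in outdir.glob("*.*"))
        manifest.status = "success"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(outdir)
        return EXIT_OK
    except CanopyGrowthError as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        manifest.status = "failed"
        manifest.failure_stage = stage
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(outdir)
        return EXIT_INFERENCE if stage in ("fit", "report") else EXIT_VALIDATION
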