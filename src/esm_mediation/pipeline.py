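"""End-to-end orchestration: data in, publication-shaped tables out.

A single :class:`RunConfig` (YAML-loadable) drives the full analysis:
load or simulate -> validity filters -> aggregates -> cross-sectional
moderated mediation in both directions -> lagged pairs -> autoregressive
and cross-lagged panel variants -> model-fit comparison.  One global seed
fans out to per-stage child seeds, so identical config + seed reproduce
every number and the manifest hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._report import (
    render_aggregates,
    render_ar_table,
    render_clpm_table,
    render_fit_comparison,
)
from .clpm import CrossLaggedPanel, compare_clpm_variants
from .data import (
    apply_compliance_filter,
    apply_lateness_filter,
    build_lagged_pairs,
    compute_aggregates,
    load_esm_table,
)
from .errors import ConfigurationError, EsmError
from .mediation import ModeratedMediation
from .montecarlo import MonteCarloEngine
from .simulate import generate_dataset, scenario

logger = logging.getLogger(__name__)

#: stage order used for seed fan-out; stable across releases
_STAGES = (
    "simulate",
    "mediation_x2y",
    "mediation_y2x",
    "clpm_ar",
    "clpm_forward",
    "clpm_reverse",
    "clpm_comprehensive",
)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    ss = np.random.SeedSequence(
        entropy=root_seed, spawn_key=(_STAGES.index(stage),)
    )
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one data source)."""

    input_path: str | None = None
    scenario: str | None = None
    n_subjects: dict | None = None  # scenario-size override
    schema: dict = field(default_factory=dict)
    max_delay: float = 15.0
    min_fraction: float = 1 / 3
    random_slopes: bool = False
    center_within: bool = False
    robust: bool = False
    mc_reps: int = 20_000
    mc_alpha: float = 0.05
    variants: tuple = ("ar", "forward", "reverse", "comprehensive")
    out_dir: str = "esm_mediation_out"
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ConfigurationError(
                "exactly one of input_path or scenario must be set"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mc = raw.pop("mc", {})
        if mc:
            raw["mc_reps"] = mc.get("reps", 20_000)
            raw["mc_alpha"] = mc.get("alpha", 0.05)
            raw["seed"] = mc.get("seed", raw.get("seed", 0))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # location does not affect results
        d.pop("verbosity")
        return json.dumps(d, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


@dataclass
class RunReport:
    """Artifacts and manifest of a completed pipeline run."""

    manifest: dict
    out_dir: Path
    aggregates: object = None
    mediation: dict = field(default_factory=dict)
    clpm: dict = field(default_factory=dict)
    fit_comparison: pd.DataFrame | None = None


class StageError(EsmError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis pipeline described by ``cfg``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    texts: dict[str, str] = {}
    report = RunReport(manifest={}, out_dir=out)

    stage = "load"
    try:
        if cfg.scenario is not None:
            stage = "simulate"
            overrides = {}
            if cfg.n_subjects:
                overrides["n_subjects"] = dict(cfg.n_subjects)
            gen_cfg = scenario(cfg.scenario, seed=stage_seed(cfg.seed, "simulate"),
                               **overrides)
            ds, truth = generate_dataset(gen_cfg)
            _write(out / "ground_truth.json", json.dumps(truth.to_json(), indent=2))
        else:
            ds = load_esm_table(cfg.input_path, schema=cfg.schema)

        stage = "filter"
        ds = apply_lateness_filter(ds, cfg.max_delay)
        ds = apply_compliance_filter(ds, cfg.min_fraction)
        ds.valid_frame().to_csv(out / "filtered_beeps.csv", index=False)
        _write(out / "filter_report.json",
               json.dumps(ds.filter_report, indent=2, default=str))

        stage = "aggregates"
        agg = compute_aggregates(ds)
        report.aggregates = agg
        agg.group_table.to_csv(out / "aggregates_groups.csv", index=False)
        agg.comparisons.to_csv(out / "aggregates_comparisons.csv", index=False)
        _write(out / "aggregates.json", json.dumps(agg.to_json(), indent=2))
        texts["aggregates"] = render_aggregates(agg)

        for direction in ("x2y", "y2x"):
            stage = f"mediation_{direction}"
            engine = MonteCarloEngine(
                reps=cfg.mc_reps, alpha=cfg.mc_alpha,
                seed=stage_seed(cfg.seed, stage),
            )
            res = ModeratedMediation(
                ds, direction=direction,
                random_slopes=cfg.random_slopes,
                center_within=cfg.center_within,
                robust=cfg.robust,
            ).fit(engine)
            report.mediation[direction] = res
            res.table().to_csv(out / f"mediation_{direction}.csv", index=False)
            _write(out / f"mediation_{direction}.json",
                   json.dumps(res.to_json(), indent=2))
            texts[f"mediation_{direction}"] = res.summary()

        stage = "lagging"
        lagged = build_lagged_pairs(ds)
        lagged.frame.to_csv(out / "lagged_pairs.csv", index=False)

        clpm_fits = {}
        for variant in cfg.variants:
            stage = f"clpm_{variant}"
            engine = MonteCarloEngine(
                reps=cfg.mc_reps, alpha=cfg.mc_alpha,
                seed=stage_seed(cfg.seed, stage),
            )
            res = CrossLaggedPanel(
                lagged, variant=variant, random_slopes=cfg.random_slopes
            ).fit(engine)
            report.clpm[variant] = res
            clpm_fits[variant] = res
            if variant == "ar":
                res.ar_table().to_csv(out / "ar_effects.csv", index=False)
                texts["ar"] = render_ar_table(res)
            else:
                res.table().to_csv(out / f"clpm_{variant}.csv", index=False)
                texts[f"clpm_{variant}"] = render_clpm_table(res)

        stage = "model_comparison"
        if len(clpm_fits) > 1:
            comp = compare_clpm_variants(clpm_fits)
            report.fit_comparison = comp
            comp.to_csv(out / "model_fit.csv", index=False)
            texts["model_fit"] = render_fit_comparison(comp)
    except EsmError:
        raise
    except Exception as exc:  # preserve partial outputs, name the stage
        raise StageError(stage, exc) from exc

    all_text = "\n\n\n".join(texts[k] for k in sorted(texts))
    _write(out / "tables.txt", all_text)

    import statsmodels

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash,
        "n_subjects_analyzed": ds.n_subjects,
        "filter_report": {
            k: v for k, v in ds.filter_report.items() if k != "rejected_rows"
        },
        "results_hash": hashlib.sha256(all_text.encode()).hexdigest(),
    }
    _write(out / "manifest.json", json.dumps(manifest, indent=2, default=str))
    report.manifest = manifest
    return report
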