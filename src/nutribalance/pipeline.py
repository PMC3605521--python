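"""End-to-end pipeline: read → close → transform → screen → diagnose → DA.

Outputs are a pure function of (input bytes, configuration, seed): every
random stage is seeded from the run configuration and each run writes a
manifest recording the input hash, parameters and produced artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balances import SBP, default_ionome_sbp, ilr, sbp_from_csv, transform_table
from .core import CompositionTable
from .diagnostics import normality_by_representation, robust_outliers_by_group, robust_outliers
from .discriminant import confidence_ellipses, fit_cda
from .errors import ConfigError, InsufficientDataError, NutribalanceError, PipelineError

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("nutribalance")

_DA_REPRESENTATIONS = ("raw", "log", "alr", "ilr")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str
    output_dir: str
    kappa: float = 100.0
    unit: str = "%"
    sbp_path: str | None = None  # None → default 5-nutrient ionome SBP
    representations: tuple[str, ...] = ("raw", "log", "alr", "ilr")
    alpha_outliers: float = 0.01
    alpha_normality: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("alpha_outliers", "alpha_normality"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {a}")
        bad = set(self.representations) - {"raw", "log", "alr", "clr", "ilr"}
        if bad:
            raise ConfigError(f"unknown representations: {sorted(bad)}")
        self.representations = tuple(self.representations)
        if not Path(self.input_path).exists():
            raise ConfigError(f"input not found: {self.input_path}")
        if self.sbp_path is not None and not Path(self.sbp_path).exists():
            raise ConfigError(f"SBP file not found: {self.sbp_path}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad run config {path}: {exc}") from None


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the manifest dict.

    Stage order: outlier screening on ilr balances (per group when groups
    are present), then normality diagnostics and discriminant analysis on
    the screened samples. Each stage's outputs are written before the next
    stage starts, so a failure leaves earlier artifacts intact.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "nutribalance",
        "version": __version__,
        "input": {"path": str(config.input_path),
                  "sha256": _sha256(config.input_path)},
        "config": {k: v for k, v in asdict(config).items()},
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    stage = "read"
    try:
        table = CompositionTable.from_csv(config.input_path, kappa=config.kappa,
                                          unit=config.unit)
        sbp = (sbp_from_csv(config.sbp_path) if config.sbp_path
               else default_ionome_sbp())
        if set(sbp.part_labels) != set(table.labels):
            table = table.subcomposition(
                [l for l in table.labels if l in sbp.part_labels]
            )
        manifest["stages"][stage] = {"n": table.n, "D": table.D,
                                     "balances": list(sbp.row_names)}

        stage = "transform"
        for rep in config.representations:
            X = transform_table(table, rep, sbp=sbp)
            path = out / f"transformed_{rep}.csv"
            X.to_csv(path, index_label="sample_id")
            manifest["outputs"].append(str(path))
        manifest["stages"][stage] = {"representations": list(config.representations)}

        stage = "outliers"
        coords = ilr(table, sbp).as_frame()
        if table.group is not None:
            mask = robust_outliers_by_group(coords, table.group,
                                            alpha=config.alpha_outliers,
                                            seed=config.seed)
        else:
            mask = robust_outliers(coords, alpha=config.alpha_outliers,
                                   seed=config.seed)
        opath = out / "outliers.csv"
        mask.as_frame().to_csv(opath, index_label="sample_id")
        manifest["outputs"].append(str(opath))
        manifest["stages"][stage] = {
            "alpha": config.alpha_outliers, "cutoff": mask.cutoff,
            "n_flagged": mask.n_flagged, "representation": "ilr",
        }
        clean = table.select(~mask.flagged)

        stage = "normality"
        reps = tuple(r for r in config.representations if r != "clr")
        report = normality_by_representation(clean, sbp,
                                             alpha=config.alpha_normality,
                                             representations=reps)
        npath = out / "normality.csv"
        report.to_csv(npath)
        (out / "normality_summary.json").write_text(
            json.dumps(report.summary(), indent=2)
        )
        manifest["outputs"] += [str(npath), str(out / "normality_summary.json")]
        manifest["stages"][stage] = report.summary()

        stage = "discriminant"
        if clean.group is not None and clean.group.nunique() >= 2:
            da_dir = out / "da"
            da_dir.mkdir(exist_ok=True)
            da_info = {}
            for rep in reps:
                X = transform_table(clean, rep, sbp=sbp)
                model = fit_cda(X, clean.group, representation=rep)
                model.scores.to_csv(da_dir / f"{rep}_scores.csv",
                                    index_label="sample_id")
                model.loadings.to_csv(da_dir / f"{rep}_loadings.csv",
                                      index_label="variable")
                pd.Series(model.eigenvalues, name="eigenvalue").to_csv(
                    da_dir / f"{rep}_eigenvalues.csv", index_label="axis"
                )
                info = {"eigenvalues": model.eigenvalues.tolist()}
                if model.n_axes >= 2:
                    ellipses = confidence_ellipses(model)
                    (da_dir / f"{rep}_ellipses.json").write_text(
                        json.dumps([e.to_dict() for e in ellipses], indent=2)
                    )
                    manifest["outputs"].append(str(da_dir / f"{rep}_ellipses.json"))
                da_info[rep] = info
                manifest["outputs"] += [
                    str(da_dir / f"{rep}_{x}.csv")
                    for x in ("scores", "loadings", "eigenvalues")
                ]
            manifest["stages"][stage] = da_info
        else:
            manifest["stages"][stage] = "skipped (need >= 2 groups)"
    except NutribalanceError as exc:
        manifest["stages"][stage] = {"error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["outputs"].append(str(out / "manifest.json"))
    return manifest
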