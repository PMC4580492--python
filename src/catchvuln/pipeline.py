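"""Config-driven pipeline: generate/load -> validate -> screen -> score ->
influence -> severity -> cluster -> compare.

Every stage writes one or more CSVs into the output directory, each with a
``# seed=...`` metadata header, and the run ends with a ``manifest.json``
listing every file with its row count.  All randomness flows from the single
config seed through named substreams, so identical config + seed gives
byte-identical outputs.  Stages can be rerun individually; a stage whose
input table is not in memory reads the previously written CSV instead of
recomputing it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering as _clustering
from . import comparison as _comparison
from . import influence as _influence
from . import scoring as _scoring
from . import severity as _severity
from . import synthetic as _synthetic
from .registry import (
    VariableSpec,
    default_registry,
    read_catchment_table,
    validate_table,
    variable_names,
    write_catchment_table,
)

logger = logging.getLogger("catchvuln")

STAGES = ("generate", "screen", "score", "influence", "severity", "cluster", "compare")

#: substream index per stage (stable even if stages are rerun selectively)
_STREAMS = {name: i for i, name in enumerate(STAGES)}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``input_path`` (a catchment CSV) or ``synthetic`` (a
    synthetic-generation section, may be an empty dict for the six default
    plays) must be given.
    """

    output_dir: Path
    seed: int = 0
    input_path: Path | None = None
    synthetic: dict | None = None
    variables: dict = dataclasses.field(default_factory=dict)
    screening: dict = dataclasses.field(default_factory=dict)
    severity_weights: dict = dataclasses.field(default_factory=dict)
    clustering: dict = dataclasses.field(default_factory=dict)
    comparison: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic must be set")
        self.output_dir = Path(self.output_dir)
        if self.input_path is not None:
            self.input_path = Path(self.input_path)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path | str = ".") -> "RunConfig":
        base = Path(base)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known - {"input"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(raw)
        if "input" in data:
            data["input_path"] = data.pop("input")
        if data.get("input_path") is not None:
            data["input_path"] = base / data["input_path"]
        data["output_dir"] = base / data.get("output_dir", "out")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=path.parent)

    def registry(self) -> dict[str, VariableSpec]:
        reg = default_registry()
        for name, overrides in self.variables.items():
            if name not in reg:
                raise ValueError(f"registry override for unknown variable {name!r}")
            spec = reg[name]
            fields = {f.name: getattr(spec, f.name) for f in dataclasses.fields(spec)}
            fields.update(overrides)
            if fields.get("breakpoints") is not None:
                fields["breakpoints"] = tuple(fields["breakpoints"])
            reg[name] = VariableSpec(**fields)
        return reg


def _profiles_from_config(section: dict) -> list[_synthetic.PlayProfile]:
    dispersion = section.get("dispersion", _synthetic.DEFAULT_DISPERSION)
    profiles = _synthetic.default_profiles(dispersion=dispersion)
    overrides = section.get("plays", {})
    out = []
    for prof in profiles:
        ov = overrides.get(prof.play_name)
        if not ov:
            out.append(prof)
            continue
        variables = dict(prof.variables)
        for var, fields in ov.get("variables", {}).items():
            current = dataclasses.asdict(variables[var])
            current.update(fields)
            variables[var] = _synthetic.VariableTarget(**current)
        out.append(
            _synthetic.PlayProfile(
                prof.play_name, ov.get("n_catchments", prof.n_catchments), variables
            )
        )
    return out


class PipelineRun:
    """One pipeline execution over a config; stage methods fill the output dir."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.registry = config.registry()
        self.outdir = config.output_dir
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, int] = {}
        self._tables: dict[str, pd.DataFrame] = {}
        self._log_path = self.outdir / "run.log"

    # -- plumbing -----------------------------------------------------------

    def _seed_for(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.config.seed, _STREAMS[stage]])

    def _write(self, name: str, table: pd.DataFrame) -> None:
        path = self.outdir / f"{name}.csv"
        write_catchment_table(table, path, metadata={"seed": self.config.seed})
        self.manifest[f"{name}.csv"] = len(table)
        logger.info("wrote %s (%d rows)", path, len(table))

    def _read(self, name: str) -> pd.DataFrame:
        if name in self._tables:
            return self._tables[name]
        path = self.outdir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"stage input {path} not found; run the producing stage first"
            )
        if name == "catchments":
            table = read_catchment_table(path, self.registry)
        else:
            table = pd.read_csv(path, comment="#", dtype={"huc12_id": str, "play": str})
        self._tables[name] = table
        return table

    def _timed(self, stage: str, fn) -> None:
        start = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            self._log(f"stage {stage} FAILED: {exc}")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        self._log(f"stage {stage} finished in {time.perf_counter() - start:.2f}s")

    def _log(self, message: str) -> None:
        logger.info(message)
        with open(self._log_path, "a") as fh:
            fh.write(f"{time.strftime('%Y-%m-%d %H:%M:%S')} {message}\n")

    # -- stages -------------------------------------------------------------

    def generate(self) -> None:
        if self.config.input_path is not None:
            table = read_catchment_table(self.config.input_path, self.registry)
        else:
            profiles = _profiles_from_config(self.config.synthetic)
            children = self._seed_for("generate").spawn(len(profiles))
            table = pd.concat(
                [
                    _synthetic.generate_play(p, c, registry=self.registry)
                    for p, c in zip(profiles, children)
                ],
                ignore_index=True,
            )
        diags = validate_table(table, self.registry)
        if diags:
            raise ValueError(f"{len(diags)} validation failures, first: {diags[0]}")
        self._tables["catchments"] = table
        self._write("catchments", table)

    def screen(self) -> None:
        table = self._read("catchments")
        threshold = self.config.screening.get("threshold", 0.6)
        flags = _scoring.screen_correlations(table, threshold, self.registry)
        frame = pd.DataFrame([dataclasses.asdict(f) for f in flags],
                             columns=["var_a", "var_b", "rho", "n"])
        self._write("screening", frame)

    def score(self) -> None:
        table = self._read("catchments")
        scores = _scoring.score_table(table, self.registry)
        self._tables["scores"] = scores
        self._write("scores", scores)

    def influence(self) -> None:
        scores = self._read("scores")
        table = self._read("catchments")
        inf = _influence.influence_table(scores, self.registry)
        self._write("influence", inf)
        uog = _influence.uog_only_scores(scores, self.registry)
        self._write("uog_scores", uog)
        wells_only = _influence.drop_no_well_variant(
            table, scores, list(_influence.UOG_VARIABLES), self.registry
        )
        self._write("influence_wells_only", wells_only)

    def severity(self) -> None:
        table = self._read("catchments")
        weights = dict(_severity.SEVERITY_WEIGHTS)
        for effect, ov in self.config.severity_weights.items():
            weights[effect] = {**weights[effect], **ov}
        rows = []
        for effect in _severity.EFFECTS:
            needed = set(_severity.EFFECT_SENSITIVITY_VARIABLES[effect]) | set(
                weights[effect]
            )
            play_means = {
                var: table.groupby("play")[var].mean().to_dict() for var in needed
            }
            results = _severity.severity_index_from_means(
                play_means, effect, weights=weights[effect]
            )
            for play, res in results.items():
                rows.append(
                    {"effect": effect, "play": play,
                     "sens_rank_sum": res.sens_rank_sum,
                     "weighted_exposure_sum": res.weighted_exposure_sum,
                     "total": res.total}
                )
        self._write("severity", pd.DataFrame(rows))

    def cluster(self) -> None:
        table = self._read("catchments")
        section = self.config.clustering
        # proximity variables are undefined in well-free catchments, so the
        # default clustering feature set is the 15 always-defined variables
        default_vars = [
            v for v in variable_names(self.registry) if not v.endswith("_proximity")
        ]
        names = section.get("variables", default_vars)
        max_points = section.get("max_points", 1000)
        lo, hi = section.get("k_range", [2, 15])

        work = table
        if len(work) > max_points:
            rng = np.random.default_rng(self._seed_for("cluster"))
            idx = np.sort(rng.choice(len(work), size=max_points, replace=False))
            work = work.iloc[idx].reset_index(drop=True)
        X = work[names].to_numpy(dtype=float)
        k, result = _clustering.select_k(X, range(lo, min(hi, len(work) - 1) + 1))
        assignments = work[["huc12_id", "play"]].copy()
        assignments["cluster"] = result.labels
        self._write("clusters", assignments)
        self._write("cluster_profiles", _clustering.cluster_profiles(result, work, self.registry))
        self._log(f"selected k={k}, avg silhouette {result.avg_silhouette:.3f}")

    def compare(self) -> None:
        scores = self._read("scores")
        section = self.config.comparison
        result = _comparison.compare_plays(
            scores,
            metrics=section.get("metrics", ("S", "E", "V")),
            alpha=section.get("alpha", _comparison.DEFAULT_ALPHA),
        )
        self._write("comparison", result)

    # -- driver -------------------------------------------------------------

    def run(self, stages: Sequence[str] | None = None) -> dict[str, int]:
        stages = list(stages) if stages is not None else list(STAGES)
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        self._log(f"run start: seed={self.config.seed}, stages={stages}")
        for stage in stages:
            self._timed(stage, getattr(self, stage))
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump({"seed": self.config.seed, "files": self.manifest}, fh, indent=2)
        self._log("run complete")
        return dict(self.manifest)


def run_pipeline(
    config: RunConfig, stages: Sequence[str] | None = None
) -> dict[str, int]:
    """Run the pipeline (all stages by default); returns file -> row count."""
    return PipelineRun(config).run(stages)
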