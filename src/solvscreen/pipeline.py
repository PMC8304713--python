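"""Full-run orchestration: simulate/ingest -> descriptors -> fit -> AD -> screen.

A run is described by a JSON-serializable :class:`RunConfig`; artifacts
(model bundle, AD report, ranked screen, run log) land in the output
directory. Every stochastic step takes an explicit seed, so two runs from
the same config are byte-identical.
"""
from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from .core_data import read_components, read_records, write_components, write_records
from .descriptors import build_feature_matrix
from .domain import LeverageDomain, williams_report
from .ensemble import SannEnsembleRegressor
from .screening import CandidateSet, enumerate_binary, enumerate_nades, screen
from .synthetic import GeneratorSpec, generate_components, generate_records


@dataclass
class RunConfig:
    out_dir: str = "run"
    components_csv: Optional[str] = None   # None -> simulate
    records_csv: Optional[str] = None
    seed: int = 0
    noise_sd: float = 0.03
    n_networks: int = 40
    rmsd_max: float = 0.04
    max_outliers: int = 4
    hidden_range: tuple[int, int] = (6, 12)
    max_attempts: int = 2000
    include_temperature: bool = True       # the seventh descriptor
    screen_category: str = "nades"         # 'binary' or 'nades'
    screen_water_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.rmsd_max <= 0:
            raise ValueError("rmsd_max must be positive")
        lo, hi = self.hidden_range
        if not (1 <= lo <= hi <= 64):
            raise ValueError("hidden_range must lie within [1, 64]")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "hidden_range" in data:
            data["hidden_range"] = tuple(data["hidden_range"])
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict of artifact paths
    and acceptance statistics. Any stage failure aborts with a stage-named
    error."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(**kv):
        line = " ".join([time.strftime("%Y-%m-%dT%H:%M:%S")]
                        + [f"{k}={v}" for k, v in kv.items()])
        log_lines.append(line)

    log(stage="start", seed=config.seed, config=json.dumps(asdict(config)))

    try:  # data
        if config.components_csv and config.records_csv:
            components = read_components(config.components_csv)
            records = read_records(config.records_csv, components)
            log(stage="ingest", n_components=len(components), n_records=len(records))
            hbd_pool = [c for c in components if c.role.value == "hbd"]
            organics = [c for c in components if c.role.value == "solvent"]
            chcl = next((c for c in components if c.name == "ChCl"), None)
            water = next((c for c in components if c.name == "water"), None)
        else:
            spec = GeneratorSpec(seed=config.seed, noise_sd=config.noise_sd)
            synth = generate_components(spec)
            records, _truth = generate_records(spec, synth)
            components = synth.all()
            write_components(components, out / "components.csv")
            write_records(records, out / "records.csv")
            log(stage="simulate", n_components=len(components), n_records=len(records))
            hbd_pool, organics = synth.hbds, synth.neat_organics
            chcl, water = synth.chcl, synth.water
    except Exception as exc:
        raise StageError("data", exc) from exc

    try:  # descriptors
        x, y = build_feature_matrix(records, include_temperature=config.include_temperature)
        log(stage="descriptors", shape=f"{x.shape[0]}x{x.shape[1]}")
    except Exception as exc:
        raise StageError("descriptors", exc) from exc

    try:  # fit
        est = SannEnsembleRegressor(
            n_networks=config.n_networks, rmsd_max=config.rmsd_max,
            max_outliers=config.max_outliers, hidden_range=config.hidden_range,
            max_attempts=config.max_attempts, random_state=config.seed).fit(x, y)
        est.save(out / "model.json")
        log(stage="fit", accepted=len(est.networks_), attempts=est.n_attempts_,
            rejected_rmsd=est.n_rejected_rmsd_,
            rejected_outliers=est.n_rejected_outliers_,
            best_rmsd=f"{est.networks_[0].rmsd:.5f}")
    except Exception as exc:
        raise StageError("fit", exc) from exc

    try:  # applicability domain
        report = williams_report(est, x, y)
        report.to_frame().to_csv(out / "ad_report.csv", index=False)
        log(stage="ad", h_star=f"{report.warning_leverage:.4f}",
            n_outside=int((~report.inside_domain).sum()))
    except Exception as exc:
        raise StageError("ad", exc) from exc

    try:  # screening
        if config.screen_category == "binary":
            grid = [i / 10 for i in range(1, 10)]
            candidates: CandidateSet = enumerate_binary(organics, grid, water=water)
        else:
            candidates = enumerate_nades(hbd_pool, chcl=chcl, water=water,
                                         water_fraction=config.screen_water_fraction)
        dom = LeverageDomain(on_singular="pinv").fit(x)
        result = screen(candidates, est, domain=dom)
        result.to_frame().to_csv(out / "ranked.csv", index=False)
        n_pred = len(candidates) * len(est.networks_)
        log(stage="screen", n_candidates=len(candidates),
            n_ranked=len(result.ranked),
            discarded_fraction=f"{result.n_discarded_predictions / max(1, n_pred):.5f}")
    except Exception as exc:
        raise StageError("screen", exc) from exc

    log(stage="done")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "out_dir": str(out),
        "artifacts": {name: str(out / name) for name in
                      ("model.json", "ad_report.csv", "ranked.csv", "run.log")},
        "n_records": len(records),
        "accepted_networks": len(est.networks_),
        "attempts": est.n_attempts_,
        "ranked_systems": len(result.ranked),
    }
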