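"""Run configuration, serialization, and the end-to-end pipeline.

All outputs are plain text (CSV/JSON) and carry provenance: every result
directory contains the exact config, its hash, and the seed, so a run is
reproducible from its own artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .params import Abundances, KineticParameters
from .sampling import SampleSpec, lhs_frame, sample_manifest, save_draws
from .scan import RobustnessConfig, histogram_matrix, mine_restrictions, run_scan

log = logging.getLogger("carousel")

_CONFIG_SECTIONS = ("kinetics", "abundances", "sampler", "robustness", "seed",
                    "variant", "n_points", "out_dir", "log_level")


@dataclass
class RunConfig:
    """Everything needed to reproduce a scan run."""

    kinetics: KineticParameters = field(default_factory=KineticParameters)
    abundances: Abundances = field(default_factory=Abundances)
    n_points: int = 1000
    seed: int = 0
    span_decades: float = 8.0
    robustness: RobustnessConfig = field(default_factory=RobustnessConfig)
    variant: str = "simplified"
    out_dir: str = "carousel_run"
    log_level: str = "INFO"

    def sample_spec(self) -> SampleSpec:
        return SampleSpec(n=self.n_points, seed=self.seed,
                          span_decades=self.span_decades,
                          reference=self.kinetics)

    def to_dict(self) -> dict:
        rb = dataclasses.asdict(self.robustness)
        rb.pop("abundances", None)
        return {
            "kinetics": self.kinetics.to_dict(),
            "abundances": {"R_tot": self.abundances.R_tot,
                           "G_tot": self.abundances.G_tot,
                           "V_cyt_fl": self.abundances.V_cyt_fl},
            "sampler": {"n": self.n_points, "seed": self.seed,
                        "span_decades": self.span_decades},
            "robustness": rb,
            "variant": self.variant,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _reject_unknown(d: dict, allowed, where: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def config_from_dict(data: dict) -> RunConfig:
    _reject_unknown(data, _CONFIG_SECTIONS, "config")
    kin = KineticParameters.from_dict(data.get("kinetics", {}))
    ab_d = dict(data.get("abundances", {}))
    _reject_unknown(ab_d, ("R_tot", "G_tot", "V_cyt_fl"), "abundances")
    ab = Abundances(**ab_d)
    smp = dict(data.get("sampler", {}))
    _reject_unknown(smp, ("n", "seed", "span_decades"), "sampler")
    rb_d = dict(data.get("robustness", {}))
    rb_fields = [f.name for f in dataclasses.fields(RobustnessConfig)
                 if f.name != "abundances"]
    _reject_unknown(rb_d, rb_fields, "robustness")
    for key in ("multipliers", "dora_band"):
        if key in rb_d:
            rb_d[key] = tuple(rb_d[key])
    rb = RobustnessConfig(abundances=ab, **rb_d)
    return RunConfig(
        kinetics=kin,
        abundances=ab,
        n_points=int(smp.get("n", 1000)),
        seed=int(smp.get("seed", 0)),
        span_decades=float(smp.get("span_decades", 8.0)),
        robustness=rb,
        variant=data.get("variant", "simplified"),
        out_dir=data.get("out_dir", "carousel_run"),
        log_level=data.get("log_level", "INFO"),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def reference_config() -> RunConfig:
    """Bundled configuration reproducing the reference parameter table."""
    ref = resources.files("carousel.data").joinpath("reference_params.yaml")
    data = yaml.safe_load(ref.read_text())
    return config_from_dict(data)


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Sample, classify, mine restrictions, and write all artifacts.

    Writes: config.yaml, manifest.json, draws.csv, labels.csv,
    fractions.json, restrictions.json, and histograms/ (per-pair CSV count
    tables for the robust-response subset when it is large enough).
    """
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    t0 = time.time()

    spec = cfg.sample_spec()
    draws = lhs_frame(spec)
    manifest = sample_manifest(spec, draws)
    manifest["config_hash"] = cfg.content_hash()
    save_config(cfg, out / "config.yaml")
    save_draws(draws, manifest, out / "draws.csv", out / "manifest.json")
    log.info("sampled %d points in %.1fs", len(draws), time.time() - t0)

    t1 = time.time()
    result = run_scan(draws, cfg.robustness)
    log.info("classified %d points in %.1fs (%d solver failures)",
             len(draws), time.time() - t1, result.n_failed)
    result.labels.to_csv(out / "labels.csv", index=False)

    fractions = dict(result.fractions)
    fractions["n"] = len(draws)
    fractions["n_failed"] = result.n_failed
    fractions["seed"] = cfg.seed
    fractions["config_hash"] = cfg.content_hash()
    with open(out / "fractions.json", "w") as fh:
        json.dump(fractions, fh, indent=2)

    robust = result.subset("robust_response")
    bounds = spec.bounds()
    payload = {"n_robust": len(robust), "restrictions": [],
               "config_hash": cfg.content_hash()}
    if len(robust) >= 50:
        restrictions = mine_restrictions(robust)
        payload["restrictions"] = [dataclasses.asdict(r) for r in restrictions]
        hm = histogram_matrix(robust[list(spec.sampled)], bounds)
        hdir = out / "histograms"
        hdir.mkdir(exist_ok=True)
        import pandas as pd
        for (x, y), counts in hm.panels.items():
            pd.DataFrame(counts.astype(int)).to_csv(
                hdir / f"{hm.panel_name(x, y)}_{x}_vs_{y}.csv", index=False)
    with open(out / "restrictions.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    log.info("pipeline done in %.1fs -> %s", time.time() - t0, out)
    return fractions
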