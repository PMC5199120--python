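"""Latin hypercube sampling of the kinetic parameter space.

The global analysis draws each kinetic parameter log-uniformly over 8
orders of magnitude centered on its reference value, with Latin hypercube
stratification (exactly one point per equal-log-width stratum per
dimension).  Kd parameters are sampled directly and on-rates re-derived
from the (koff, Kd) pairs, so the model's thermodynamic symmetry holds at
every sampled point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import __version__
from .params import PARAMETER_NAMES, REFERENCE, KineticParameters

#: Default sampled set: all 12 kinetic parameters, kH_LRGt as its own axis.
DEFAULT_SAMPLED: tuple[str, ...] = PARAMETER_NAMES


@dataclass(frozen=True)
class SampleSpec:
    """Specification of one Latin hypercube draw of kinetic parameters."""

    n: int = 100_000
    seed: int = 0
    span_decades: float = 8.0
    sampled: tuple[str, ...] = DEFAULT_SAMPLED
    reference: KineticParameters = field(default_factory=KineticParameters)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.span_decades <= 0:
            raise ValueError("span must be positive")
        if not self.sampled:
            raise ValueError("sampled parameter set must be non-empty")
        unknown = set(self.sampled) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")

    def bounds(self) -> dict[str, tuple[float, float]]:
        """Per-parameter (low, high) bounds in linear units."""
        half = self.span_decades / 2.0
        out = {}
        for name in self.sampled:
            c = getattr(self.reference, name)
            out[name] = (c * 10.0 ** -half, c * 10.0 ** half)
        return out


def lhs_frame(spec: SampleSpec) -> pd.DataFrame:
    """Latin hypercube draws as a DataFrame (one row per point).

    Non-sampled parameters are fixed at their reference values, so every
    row is a complete kinetic parameter set.
    """
    d = len(spec.sampled)
    sampler = qmc.LatinHypercube(d=d, seed=spec.seed)
    u = sampler.random(spec.n)
    half = spec.span_decades / 2.0
    centers = np.array([getattr(spec.reference, nm) for nm in spec.sampled])
    logs = np.log10(centers)[None, :] - half + u * spec.span_decades
    frame = pd.DataFrame(10.0 ** logs, columns=list(spec.sampled))
    for name in PARAMETER_NAMES:
        if name not in spec.sampled:
            frame[name] = getattr(spec.reference, name)
    return frame[list(PARAMETER_NAMES)]


def lhs_sample(spec: SampleSpec) -> list[KineticParameters]:
    """Latin hypercube draws as a list of parameter sets."""
    frame = lhs_frame(spec)
    return frame_to_params(frame)


def frame_to_params(frame: pd.DataFrame) -> list[KineticParameters]:
    return [KineticParameters(**row) for row in frame.to_dict("records")]


def params_to_frame(draws: list[KineticParameters]) -> pd.DataFrame:
    return pd.DataFrame([p.to_dict() for p in draws], columns=list(PARAMETER_NAMES))


def sample_manifest(spec: SampleSpec, draws: pd.DataFrame | list[KineticParameters]) -> dict:
    """Provenance record: spec, per-parameter ranges, package version."""
    if not isinstance(draws, pd.DataFrame):
        draws = params_to_frame(draws)
    return {
        "package_version": __version__,
        "n": int(spec.n),
        "seed": int(spec.seed),
        "span_decades": float(spec.span_decades),
        "sampled": list(spec.sampled),
        "reference": spec.reference.to_dict(),
        "bounds": {k: list(v) for k, v in spec.bounds().items()},
        "n_rows": int(len(draws)),
    }


def spec_from_manifest(manifest: dict) -> SampleSpec:
    """Rebuild the sampling spec (and hence the draws) from a manifest."""
    return SampleSpec(
        n=manifest["n"],
        seed=manifest["seed"],
        span_decades=manifest["span_decades"],
        sampled=tuple(manifest["sampled"]),
        reference=KineticParameters.from_dict(manifest["reference"]),
    )


def save_draws(frame: pd.DataFrame, manifest: dict, csv_path, manifest_path) -> None:
    frame.to_csv(csv_path, index=False)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
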