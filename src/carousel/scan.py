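"""Robustness classification, global scans, and restriction mining.

A parameter point "measures fractional occupancy" when its free-Gbg
dose-response is insensitive to the total receptor abundance.  Each point
is classified by simulating the curve at receptor multipliers {0.1, 1, 10}:

``normal_amplitude``
    the reference-abundance amplitude reaches a minimal normalized output;
``robust_amplitude`` / ``robust_ec50``
    the amplitude (EC50) varies less than a tolerated fold-change across
    the three abundances;
``robust_response``
    both partial behaviors at once — the main object of the scan;
``dora``
    dose-response alignment: the output EC50 matches the occupancy EC50
    (which the model pins at the ligand Kd) within a fold-band, evaluated
    at reference abundance.

Restriction mining then looks for pairwise order relations (x << y) that
hold in (nearly) all points of a behavioral class: those are the parameter
inequalities the behavior requires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import adaptive_grid, default_grid, ec50, simulate_dor
from .network import build_network
from .params import PARAMETER_NAMES, Abundances, KineticParameters
from .steady_state import DEFAULT_TOL

LABEL_COLUMNS = (
    "normal_amplitude", "robust_amplitude", "robust_ec50",
    "robust_response", "dora", "any_failure",
)


@dataclass(frozen=True)
class RobustnessConfig:
    """Classification thresholds and simulation settings."""

    multipliers: tuple[float, ...] = (0.1, 1.0, 10.0)
    amplitude_ratio_max: float = 1.5   # max/min amplitude fold across multipliers
    ec50_ratio_max: float = 3.0        # max/min EC50 fold across multipliers
    min_amplitude: float = 0.05        # normal-amplitude floor, normalized output
    dora_band: tuple[float, float] = (1.0 / 3.0, 3.0)
    abundances: Abundances = field(default_factory=Abundances)
    grid_points: int = 25
    adaptive: bool = True              # center the ligand grid on each point's Kd_LR
    grid_decades_below: float = 3.0
    grid_decades_above: float = 4.0
    tol: float = DEFAULT_TOL
    exclude_failures: bool = False     # drop failed points from denominators

    def __post_init__(self) -> None:
        if 1.0 not in self.multipliers:
            raise ValueError("multipliers must include the reference (1)")
        if self.amplitude_ratio_max <= 1 or self.ec50_ratio_max <= 1:
            raise ValueError("ratio tolerances must exceed 1")

    def grid(self, params: KineticParameters) -> np.ndarray:
        if self.adaptive:
            return adaptive_grid(params.Kd_LR, self.grid_points,
                                 self.grid_decades_below, self.grid_decades_above)
        return default_grid(self.grid_points)


@dataclass(frozen=True)
class RobustnessLabel:
    normal_amplitude: bool
    robust_amplitude: bool
    robust_ec50: bool
    robust_response: bool
    dora: bool
    any_failure: bool
    amplitudes: tuple[float, ...] = ()
    ec50s: tuple[float, ...] = ()
    dora_ratio: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "normal_amplitude": self.normal_amplitude,
            "robust_amplitude": self.robust_amplitude,
            "robust_ec50": self.robust_ec50,
            "robust_response": self.robust_response,
            "dora": self.dora,
            "any_failure": self.any_failure,
            "dora_ratio": self.dora_ratio,
        }


@dataclass(frozen=True)
class Restriction:
    """Pairwise order relation log10(x) < log10(y) - margin within a subset."""

    x: str
    y: str
    fraction: float
    necessary: bool
    margin_decades: float = 0.0


@dataclass
class ScanResult:
    draws: pd.DataFrame
    labels: pd.DataFrame
    fractions: dict[str, float]
    n_failed: int
    config: RobustnessConfig
    restrictions: list[Restriction] = field(default_factory=list)

    def subset(self, flag: str) -> pd.DataFrame:
        """Parameter rows of the points carrying a given label flag."""
        return self.draws.loc[self.labels[flag].to_numpy()]


def _failure_label() -> RobustnessLabel:
    return RobustnessLabel(False, False, False, False, False, True)


def classify_point(params: KineticParameters,
                   config: RobustnessConfig | None = None) -> RobustnessLabel:
    """Classify one parameter point for robustness to receptor abundance.

    Simulates the dose-response curve at each receptor-abundance
    multiplier.  Solver failures at any multiplier make the point
    non-robust and set ``any_failure``.  Points that never reach the
    normal-amplitude floor at reference abundance are non-robust without
    simulating the remaining multipliers.
    """
    config = config or RobustnessConfig()
    net = build_network("simplified", params)
    grid = config.grid(params)

    ref_ab = config.abundances
    curve = simulate_dor(net, ref_ab, grid, tol=config.tol)
    if not curve.all_converged:
        return _failure_label()
    amp_ref = float(curve.output[-1] - curve.output[0])
    e_out = ec50(grid, curve.output, min_amplitude=config.min_amplitude,
                 converged=curve.converged)
    e_occ = ec50(grid, curve.occupancy, converged=curve.converged)
    ratio = e_out / e_occ if np.isfinite(e_out) and np.isfinite(e_occ) else float("nan")
    dora = bool(np.isfinite(ratio)
                and config.dora_band[0] <= ratio <= config.dora_band[1])

    normal = amp_ref >= config.min_amplitude
    if not normal:
        return RobustnessLabel(False, False, False, False, dora, False,
                               (amp_ref,), (e_out,), ratio)

    amps, ecs, failed = [amp_ref], [e_out], False
    for m in config.multipliers:
        if m == 1.0:
            continue
        c = simulate_dor(net, ref_ab.with_receptor_multiplier(m), grid,
                         tol=config.tol)
        if not c.all_converged:
            failed = True
            break
        amps.append(float(c.output[-1] - c.output[0]))
        ecs.append(ec50(grid, c.output, min_amplitude=config.min_amplitude,
                        converged=c.converged))
    if failed:
        return _failure_label()

    amps_arr = np.asarray(amps)
    if np.all(amps_arr > 0):
        robust_amp = bool(amps_arr.max() / amps_arr.min() <= config.amplitude_ratio_max)
    else:
        robust_amp = False
    ecs_arr = np.asarray(ecs)
    if np.all(np.isfinite(ecs_arr)):
        robust_ec = bool(ecs_arr.max() / ecs_arr.min() <= config.ec50_ratio_max)
    else:
        robust_ec = False
    return RobustnessLabel(
        normal_amplitude=True,
        robust_amplitude=robust_amp,
        robust_ec50=robust_ec,
        robust_response=robust_amp and robust_ec,
        dora=dora,
        any_failure=False,
        amplitudes=tuple(amps),
        ec50s=tuple(float(e) for e in ecs),
        dora_ratio=float(ratio) if np.isfinite(ratio) else float("nan"),
    )


def run_scan(draws: pd.DataFrame | list[KineticParameters],
             config: RobustnessConfig | None = None,
             progress: bool = False) -> ScanResult:
    """Classify every draw and aggregate class fractions.

    Deterministic given the draws and config.  Failed points stay in the
    denominators unless ``config.exclude_failures`` is set; either way the
    failure count is reported.
    """
    config = config or RobustnessConfig()
    if not isinstance(draws, pd.DataFrame):
        from .sampling import params_to_frame
        draws = params_to_frame(draws)
    draws = draws.reset_index(drop=True)

    rows = []
    iterator = draws.itertuples(index=False)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, total=len(draws))
    for row in iterator:
        p = KineticParameters(**{nm: getattr(row, nm) for nm in PARAMETER_NAMES})
        rows.append(classify_point(p, config).as_dict())
    labels = pd.DataFrame(rows)

    n_failed = int(labels["any_failure"].sum())
    denom_mask = ~labels["any_failure"] if config.exclude_failures \
        else np.ones(len(labels), dtype=bool)
    denom = max(int(denom_mask.sum()), 1)
    fractions = {flag: float((labels[flag] & denom_mask).sum() / denom)
                 for flag in LABEL_COLUMNS if flag != "any_failure"}
    robust = labels["robust_response"]
    fractions["dora_given_robust"] = (
        float((robust & labels["dora"]).sum() / robust.sum()) if robust.any()
        else float("nan"))
    fractions["failed"] = float(n_failed / max(len(labels), 1))
    return ScanResult(draws, labels, fractions, n_failed, config)


# ---------------------------------------------------------------------------
# histograms and restriction mining
# ---------------------------------------------------------------------------

@dataclass
class HistogramMatrix:
    """Per-parameter-pair 2D log10 histograms plus diagonal 1D histograms."""

    parameters: tuple[str, ...]
    edges: dict[str, np.ndarray]
    panels: dict[tuple[str, str], np.ndarray]
    diagonals: dict[str, np.ndarray]

    def panel_name(self, x: str, y: str) -> str:
        """Row-major panel tag (R<row><col>) for cross-reference in reports."""
        i = self.parameters.index(y)
        j = self.parameters.index(x)
        return f"R{i}{j}"


def histogram_matrix(points: pd.DataFrame, bounds: dict[str, tuple[float, float]],
                     decades_per_bin: float = 1.0) -> HistogramMatrix:
    """Matrix of pairwise 2D histograms of log10 parameter values.

    Bin edges tile each parameter's sampled range in ``decades_per_bin``
    steps.  The diagonal holds the 1D histograms; marginal sums of every
    panel reproduce them.
    """
    if len(points) == 0:
        raise ValueError("empty point set")
    names = [c for c in points.columns if c in bounds]
    edges = {}
    for nm in names:
        lo, hi = np.log10(bounds[nm][0]), np.log10(bounds[nm][1])
        nbin = max(int(np.ceil((hi - lo) / decades_per_bin)), 1)
        edges[nm] = lo + np.arange(nbin + 1) * decades_per_bin
    logs = {nm: np.log10(points[nm].to_numpy()) for nm in names}
    panels = {}
    for x, y in itertools.permutations(names, 2):
        h, _, _ = np.histogram2d(logs[x], logs[y], bins=(edges[x], edges[y]))
        panels[(x, y)] = h
    diagonals = {nm: np.histogram(logs[nm], bins=edges[nm])[0] for nm in names}
    return HistogramMatrix(tuple(names), edges, panels, diagonals)


def mine_restrictions(points: pd.DataFrame, parameters: list[str] | None = None,
                      threshold: float = 0.95, min_points: int = 50,
                      margin_decades: float = 0.0) -> list[Restriction]:
    """Pairwise order restrictions satisfied by >= threshold of the subset.

    For every ordered parameter pair the exact fraction of points with
    log10(x) < log10(y) - margin is counted; pairs at or above the
    threshold are reported, and fraction-1 pairs flagged *necessary*.
    """
    if len(points) < min_points:
        raise ValueError(
            f"subset of {len(points)} points is below the minimum of {min_points}; "
            "restrictions would not be statistically meaningful")
    names = parameters or [c for c in points.columns if c in PARAMETER_NAMES]
    logs = {nm: np.log10(points[nm].to_numpy()) for nm in names}
    out = []
    for x, y in itertools.permutations(names, 2):
        frac = float(np.mean(logs[x] < logs[y] - margin_decades))
        if frac >= threshold:
            out.append(Restriction(x, y, frac, frac == 1.0, margin_decades))
    return sorted(out, key=lambda r: (-r.fraction, r.x, r.y))


@dataclass
class DoraSubanalysis:
    dora_fraction: float
    n_robust: int
    n_dora: int
    #: among robust & DoRA points: koff_RG > koff_LR group ("collision") and
    #: its complement ("precoupled"), with the fraction of each group whose
    #: kH_LRGt lies within one decade of the group's pacing off-rate
    n_collision: int
    n_precoupled: int
    frac_hydrolysis_paced: float
    frac_r07: float            # koff_LR < kH_LRGt among robust & DoRA


def dora_subanalysis(robust_points: pd.DataFrame,
                     dora_flags: np.ndarray) -> DoraSubanalysis:
    """Structure of DoRA within the robust-response subset.

    DoRA requires roughly one hydrolysis event per ternary-complex
    lifetime: kH_LRGt ~ max(koff_LR, koff_RG).  The subset splits by which
    off-rate paces the complex, and the analysis reports how often the
    occupied-receptor hydrolysis rate tracks that pace within one decade,
    plus the koff_LR < kH_LRGt necessity.
    """
    if len(robust_points) == 0:
        raise ValueError("empty robust subset")
    dora_flags = np.asarray(dora_flags, dtype=bool)
    n = len(robust_points)
    nd = int(dora_flags.sum())
    sub = robust_points.loc[dora_flags]
    if nd:
        k_lr = sub["koff_LR"].to_numpy()
        k_rg = sub["koff_RG"].to_numpy()
        k_h = sub["kH_LRGt"].to_numpy()
        collision = k_rg > k_lr
        pace = np.maximum(k_lr, k_rg)
        paced = np.abs(np.log10(k_h) - np.log10(pace)) <= 1.0
        frac_paced = float(paced.mean())
        frac_r07 = float((k_lr < k_h).mean())
        n_col, n_pre = int(collision.sum()), int((~collision).sum())
    else:
        frac_paced = float("nan")
        frac_r07 = float("nan")
        n_col = n_pre = 0
    return DoraSubanalysis(nd / n, n, nd, n_col, n_pre, frac_paced, frac_r07)
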