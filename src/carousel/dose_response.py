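"""Dose-response simulation and summary statistics.

The model output is free Gbg normalized to total G protein; the input axis
is the clamped extracellular ligand concentration.  Curves are computed as
one steady state per grid point, marching up the ligand grid with the
previous solution as the starting guess (continuation), which keeps the
Newton path fast and stable.

Also provides the classical receptor-theory baseline
E/Em = f(S) = S/(Ke + S) with stimulus S = eps*[R0]*[L]/(Kd + [L]), against
which the carousel model's robustness to receptor abundance is contrasted:
in the classical formula the EC50 always drops as R0 rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork, occupancy
from .params import Abundances
from .steady_state import DEFAULT_TOL, initial_state, solve_steady_state

#: Default ligand grid: 0 plus 25 log-spaced points over [1e-3, 1e5] nM.
def default_grid(n_points: int = 25, lo: float = 1e-3, hi: float = 1e5) -> np.ndarray:
    return np.concatenate([[0.0], np.logspace(np.log10(lo), np.log10(hi), n_points)])


def adaptive_grid(Kd_LR: float, n_points: int = 25,
                  decades_below: float = 3.0, decades_above: float = 4.0) -> np.ndarray:
    """Grid centered on the ligand Kd, with a saturating top at Kd*10^above."""
    lo = Kd_LR * 10.0 ** -decades_below
    hi = Kd_LR * 10.0 ** decades_above
    return np.concatenate([[0.0], np.logspace(np.log10(lo), np.log10(hi), n_points)])


@dataclass
class DoRCurve:
    """One steady-state dose-response curve."""

    L: np.ndarray                 # nM, sorted, L[0] == 0
    output: np.ndarray            # free Gbg / G_tot
    occupancy: np.ndarray         # occupied receptor / R_tot
    converged: np.ndarray         # bool per point
    R_tot: float
    G_tot: float
    states: np.ndarray | None = field(default=None, repr=False)

    @property
    def all_converged(self) -> bool:
        return bool(np.all(self.converged))


@dataclass
class DoRSummary:
    basal: float
    amplitude: float
    ec50_output: float            # nM; nan when undefined
    ec50_occupancy: float         # nM
    dora_ratio: float             # nan when undefined
    converged: bool


def simulate_dor(network: ReactionNetwork, abundances: Abundances,
                 L_grid: np.ndarray | None = None, *, tol: float = DEFAULT_TOL,
                 init: np.ndarray | None = None,
                 keep_states: bool = False) -> DoRCurve:
    """Steady-state dose-response curve over a ligand grid.

    The grid must be sorted and start at 0 (the unliganded baseline).
    Solver failures are recorded per point and propagated as flags.
    """
    if L_grid is None:
        L_grid = default_grid()
    L_grid = np.asarray(L_grid, dtype=float)
    if L_grid[0] != 0.0 or np.any(np.diff(L_grid) <= 0):
        raise ValueError("ligand grid must be sorted and start at 0")

    if init is None:
        init = initial_state(network, abundances, tol)
    x = np.asarray(init, dtype=float)

    n = len(L_grid)
    out = np.empty(n)
    occ = np.empty(n)
    conv = np.zeros(n, dtype=bool)
    states = np.empty((n, len(network.species))) if keep_states else None
    G_tot = abundances.G_tot
    for i, L in enumerate(L_grid):
        ss = solve_steady_state(network, L, x, tol)
        conv[i] = ss.converged
        out[i] = ss.state[network.groups["gbg_free"][0]] / G_tot if G_tot > 0 else 0.0
        occ[i] = occupancy(network, ss.state, abundances.R_tot)
        if keep_states:
            states[i] = ss.state
        if ss.converged:
            x = ss.state          # continuation along the grid
    return DoRCurve(L_grid, out, occ, conv, abundances.R_tot, G_tot, states)


def amplitude(curve: DoRCurve) -> float:
    """Output at saturating ligand minus basal output; nan if endpoints failed."""
    if not (curve.converged[0] and curve.converged[-1]):
        return float("nan")
    return float(curve.output[-1] - curve.output[0])


def ec50(L: np.ndarray, series: np.ndarray, *, min_amplitude: float = 0.0,
         converged: np.ndarray | None = None) -> float:
    """Half-maximal ligand concentration by log-linear interpolation.

    The series is baseline-subtracted and normalized by its endpoint
    amplitude; the first upward crossing of 0.5 is interpolated in log10(L).
    Returns nan when the amplitude is below ``min_amplitude`` (no
    well-defined half-max) or when endpoints did not converge.
    """
    L = np.asarray(L, dtype=float)
    series = np.asarray(series, dtype=float)
    if converged is not None and not (converged[0] and converged[-1]):
        return float("nan")
    amp = series[-1] - series[0]
    if not np.isfinite(amp) or amp <= max(min_amplitude, 0.0) or amp == 0.0:
        return float("nan")
    y = (series - series[0]) / amp
    above = np.nonzero(y[1:] >= 0.5)[0]
    if len(above) == 0:
        return float("nan")
    k = above[0] + 1          # first grid point at/above half-max
    if k == 1:                # crossing below the first positive grid point
        return float(L[1])
    lo, hi = L[k - 1], L[k]
    f = (0.5 - y[k - 1]) / (y[k] - y[k - 1])
    return float(10.0 ** (np.log10(lo) + f * (np.log10(hi) - np.log10(lo))))


def dora_ratio(curve: DoRCurve, *, min_amplitude: float = 0.0,
               band: tuple[float, float] = (1.0 / 3.0, 3.0)) -> tuple[float, bool]:
    """EC50(output) / EC50(occupancy), and whether it falls in the DoRA band."""
    e_out = ec50(curve.L, curve.output, min_amplitude=min_amplitude,
                 converged=curve.converged)
    e_occ = ec50(curve.L, curve.occupancy, converged=curve.converged)
    if not (np.isfinite(e_out) and np.isfinite(e_occ)):
        return float("nan"), False
    ratio = e_out / e_occ
    return ratio, bool(band[0] <= ratio <= band[1])


def summarize(curve: DoRCurve, *, min_amplitude: float = 0.0,
              band: tuple[float, float] = (1.0 / 3.0, 3.0)) -> DoRSummary:
    amp = amplitude(curve)
    ratio, _ = dora_ratio(curve, min_amplitude=min_amplitude, band=band)
    return DoRSummary(
        basal=float(curve.output[0]),
        amplitude=amp,
        ec50_output=ec50(curve.L, curve.output, min_amplitude=min_amplitude,
                         converged=curve.converged),
        ec50_occupancy=ec50(curve.L, curve.occupancy, converged=curve.converged),
        dora_ratio=ratio,
        converged=curve.all_converged,
    )


# ---------------------------------------------------------------------------
# classical receptor-theory baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReceptorTheoryParams:
    """Parameters of the operational receptor-theory transfer function."""

    R0: float = 1.0       # receptor abundance, arbitrary concentration units
    Kd: float = 10.0      # ligand-receptor dissociation constant
    epsilon: float = 1.0  # intrinsic efficacy
    Ke: float = 0.1       # transducer constant

    def __post_init__(self) -> None:
        for name in ("R0", "Kd", "epsilon", "Ke"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive")


def receptor_theory_effect(L, p: ReceptorTheoryParams):
    """Normalized effect E/Em = S/(Ke+S) with S = eps*R0*L/(Kd+L)."""
    L = np.asarray(L, dtype=float)
    S = p.epsilon * p.R0 * L / (p.Kd + L)
    out = S / (p.Ke + S)
    return out if out.ndim else float(out)
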