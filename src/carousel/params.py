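"""Kinetic parameters and abundances for the carousel model.

The carousel model couples the ternary-complex description of a GPCR
(ligand L, receptor R, and their complexes with the G protein) to a
three-state G-protein activation cycle.  The simplified model is fully
specified by twelve rate/affinity constants plus two total abundances
(receptor and G protein).  Reference values correspond to the yeast
pheromone response system (Ste2/Gpa1/Ste4-Ste18, with Sst2 RGS activity
folded into receptor-coupled hydrolysis rates).

Units: concentrations in nM, time in s.  Bimolecular rate constants are in
nM^-1 s^-1.  Molecule counts appear only at I/O boundaries and are
converted through the cytosolic volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

AVOGADRO = 6.02214076e23

#: Reference cytosolic volume used for molecule-count conversions (fl).
V_CYT_FL = 36.4


def molecules_to_nM(count: float, volume_fl: float = V_CYT_FL) -> float:
    """Convert a per-cell molecule count to a concentration in nM."""
    if count < 0:
        raise ValueError("molecule count must be non-negative")
    if volume_fl <= 0:
        raise ValueError("cell volume must be positive")
    return count / (AVOGADRO * volume_fl * 1e-15) * 1e9


def nM_to_molecules(conc_nM: float, volume_fl: float = V_CYT_FL) -> float:
    """Inverse of :func:`molecules_to_nM`."""
    if conc_nM < 0:
        raise ValueError("concentration must be non-negative")
    if volume_fl <= 0:
        raise ValueError("cell volume must be positive")
    return conc_nM * 1e-9 * AVOGADRO * volume_fl * 1e-15


def _check_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Rate and affinity constants of the simplified carousel model.

    Defaults are the reference values for the yeast pheromone response.
    ``kH_LRGt`` (hydrolysis of GaGTP coupled to a ligand-occupied receptor)
    defaults to ``kH_RGt``, reflecting the assumption that the
    receptor-associated RGS accelerates hydrolysis regardless of the
    receptor's occupancy state.

    Derived on-rates are re-computed from the (koff, Kd) pairs so that the
    thermodynamic symmetry assumptions hold at any parameter point.
    """

    Kd_LR: float = 5.6        # nM
    koff_LR: float = 0.001    # 1/s
    Kd_RG: float = 33.0       # nM
    koff_RG: float = 0.1      # 1/s
    Kd_GdGbg: float = 0.01    # nM
    kA_Gd: float = 3.2        # 1/(nM s)
    kE_G: float = 0.00062     # 1/s
    kE_RG: float = 0.00062    # 1/s
    kE_LRG: float = 1.5       # 1/s
    kH_Gt: float = 0.002      # 1/s
    kH_RGt: float = 0.11      # 1/s
    kH_LRGt: float | None = None  # 1/s; defaults to kH_RGt

    def __post_init__(self) -> None:
        if self.kH_LRGt is None:
            object.__setattr__(self, "kH_LRGt", self.kH_RGt)
        for f in fields(self):
            _check_positive(f.name, getattr(self, f.name))

    @property
    def kon_LR(self) -> float:
        """Ligand-receptor on-rate, 1/(nM s)."""
        return self.koff_LR / self.Kd_LR

    @property
    def kon_RG(self) -> float:
        """Receptor-Ga coupling on-rate, 1/(nM s)."""
        return self.koff_RG / self.Kd_RG

    @property
    def koff_GdGbg(self) -> float:
        """GaGDP-Gbg trimer dissociation rate, 1/s."""
        return self.kA_Gd * self.Kd_GdGbg

    def replace(self, **changes: float) -> "KineticParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown kinetic parameter(s): {sorted(unknown)}")
        return cls(**d)


#: Names of the 12 kinetic parameters, in canonical order.
PARAMETER_NAMES: tuple[str, ...] = tuple(f.name for f in fields(KineticParameters))

#: Reference (wild-type) parameter point.
REFERENCE = KineticParameters()


@dataclass(frozen=True)
class Abundances:
    """Total receptor and G-protein concentrations (nM).

    Ga total equals Gbg total (the G protein is produced as a heterotrimer).
    """

    R_tot: float = 1400.0
    G_tot: float = 860.0
    V_cyt_fl: float = V_CYT_FL

    def __post_init__(self) -> None:
        if self.R_tot < 0 or self.G_tot < 0:
            raise ValueError("total abundances must be non-negative")
        if self.V_cyt_fl <= 0:
            raise ValueError("cell volume must be positive")

    def with_receptor_multiplier(self, m: float) -> "Abundances":
        return replace(self, R_tot=self.R_tot * m)

    @property
    def R_tot_molecules(self) -> float:
        return nM_to_molecules(self.R_tot, self.V_cyt_fl)

    @property
    def G_tot_molecules(self) -> float:
        return nM_to_molecules(self.G_tot, self.V_cyt_fl)


@dataclass(frozen=True)
class ExtendedRGSParameters:
    """Additions for the extended model with explicit RGS-receptor binding.

    In the extended variant each receptor form exists in an RGS-free and an
    RGS-bound state.  Receptor-coupled GaGTP is hydrolyzed at the
    accelerated (GAP-stimulated) rate only on RGS-bound receptors; on
    RGS-free receptors it proceeds at ``kH_noRGS_RGt`` (the basal rate).
    """

    RGS_tot_molecules: float = 6000.0
    Kd_R_RGS: float = 383.0        # nM
    kH_noRGS_RGt: float = 0.002    # 1/s
    kon_R_RGS: float = 0.01        # 1/(nM s)
    V_cyt_fl: float = V_CYT_FL

    def __post_init__(self) -> None:
        _check_positive("RGS_tot_molecules", self.RGS_tot_molecules)
        _check_positive("Kd_R_RGS", self.Kd_R_RGS)
        _check_positive("kH_noRGS_RGt", self.kH_noRGS_RGt)
        _check_positive("kon_R_RGS", self.kon_R_RGS)
        _check_positive("V_cyt_fl", self.V_cyt_fl)

    @property
    def koff_R_RGS(self) -> float:
        return self.kon_R_RGS * self.Kd_R_RGS

    @property
    def RGS_tot_nM(self) -> float:
        return molecules_to_nM(self.RGS_tot_molecules, self.V_cyt_fl)


@dataclass(frozen=True)
class TwoPoolSpec:
    """Second receptor pool for dominant-negative simulations.

    Pool-2 receptors couple the G protein with the same rates as pool 1 but
    cannot bind ligand (a non-binder allele); their coupled Ga is subject to
    the unoccupied-receptor exchange and hydrolysis rates.
    """

    R_tot2: float = 700.0
    binds_ligand: bool = False

    def __post_init__(self) -> None:
        if self.R_tot2 < 0:
            raise ValueError("R_tot2 must be non-negative")
        if self.binds_ligand:
            raise ValueError(
                "a ligand-binding second pool is identical to enlarging pool 1; "
                "use a single pool instead"
            )
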