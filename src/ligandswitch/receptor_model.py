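"""Mass-action ODE model of ligand-driven EGFR activation and trafficking.

The model tracks five receptor pools on a dimensionless scale (the ligand-free
surface pool of an EGF-cultured cell is 1):

    Rs  free surface receptor
    Cs  surface ligand-receptor complex, unphosphorylated
    Ps  phosphorylated surface complex
    Pi  internalized phosphorylated receptor
    Ri  internalized non-phosphorylated receptor

Reactions: reversible ligand binding (``kon``/``koff``), phosphorylation /
dephosphorylation at the surface (``kp``/``kdp``), constitutive internalization
of free receptor (``ke0``), induced internalization of phosphorylated complex
(``ke1``), internal dephosphorylation (``kdpi``), recycling (``kr``),
degradation of internal receptor (``kdeg``, ``kdegP``) and constitutive
synthesis of surface receptor (``vs``).  Ligand in the medium is held constant
(bulk volume vastly exceeds cellular binding capacity at nanomolar doses).

EGF and amphiregulin (AREG) are modelled identically except for their
equilibrium dissociation constants: kd(AREG) = 10 x kd(EGF).  This is the
model's core assumption — signal strength differences between the two ligands
arise from affinity alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "LigandSpec",
    "ReceptorModelParams",
    "ModelState",
    "Trajectory",
    "NonConvergentEquilibriumError",
    "IntegrationError",
    "InvalidReadoutError",
    "KD_EGF_NM",
    "KD_AREG_NM",
    "AFFINITY_RATIO",
    "egf",
    "areg",
    "default_params",
    "synthesis_rate_for_unit_pool",
    "initial_steady_state",
    "simulate",
    "readout",
    "READOUT_KINDS",
]

SPECIES = ("Rs", "Cs", "Ps", "Pi", "Ri")

#: Packaged dissociation constants (nM).  The 10-fold affinity ratio between
#: EGF and AREG is fixed; the absolute EGF value is a calibration choice.
KD_EGF_NM = 20.0
AFFINITY_RATIO = 10.0
KD_AREG_NM = KD_EGF_NM * AFFINITY_RATIO

#: Pools summed by :func:`readout`.  "pEGFR_total" corresponds to a
#: whole-lysate phospho-EGFR blot (surface + internalized phospho receptor);
#: "surface_EGFR" to surface biotinylation / staining; "total_EGFR" to a total
#: EGFR blot.
READOUT_KINDS = {
    "pEGFR_total": ("Ps", "Pi"),
    "surface_EGFR": ("Rs", "Cs", "Ps"),
    "total_EGFR": ("Rs", "Cs", "Ps", "Pi", "Ri"),
}

_NEG_TOL = 1e-9  # absolute tolerance on negative integrator output


class NonConvergentEquilibriumError(ValueError):
    """The ligand-free system has no finite steady state."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed or produced a negative state."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class InvalidReadoutError(KeyError):
    """Unknown readout kind."""


@dataclass(frozen=True)
class LigandSpec:
    """A ligand dose: name, medium concentration (nM) and affinity (kd, nM)."""

    name: str
    concentration: float
    kd: float

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("ligand concentration must be >= 0")
        if self.kd <= 0:
            raise ValueError("ligand kd must be > 0")


def egf(concentration: float, kd: float = KD_EGF_NM) -> LigandSpec:
    return LigandSpec("EGF", concentration, kd)


def areg(concentration: float, kd: float = KD_AREG_NM) -> LigandSpec:
    return LigandSpec("AREG", concentration, kd)


@dataclass(frozen=True)
class ReceptorModelParams:
    """Rate constants of the trafficking network (per minute; kon per nM per
    minute; vs in receptor units per minute).

    ``r_scale`` multiplies the pre-stimulation receptor pools: 1 for the
    EGF-cultured (E-cell) scenario, 10 for the AREG-cultured (A-cell) surface
    scenario.
    """

    kon: float = 0.1
    kp: float = 0.05
    kdp: float = 0.3
    ke0: float = 0.02
    ke1: float = 0.1
    kdpi: float = 0.1
    kr: float = 0.05
    kdeg: float = 0.02
    kdegP: float = 0.1
    vs: float = field(default=0.0)
    r_scale: float = 1.0

    def __post_init__(self):
        for name in ("kon", "kp", "kdp", "ke0", "ke1", "kdpi", "kr", "kdeg",
                     "kdegP", "vs", "r_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ke1 < self.ke0:
            raise ValueError("induced internalization ke1 must be >= ke0")

    def koff(self, ligand: LigandSpec) -> float:
        """Dissociation rate implied by the shared kon and the ligand's kd."""
        return self.kon * ligand.kd


def synthesis_rate_for_unit_pool(ke0: float, kr: float, kdeg: float) -> float:
    """Synthesis rate vs that places the ligand-free surface pool at 1."""
    if ke0 <= 0 or kdeg <= 0:
        raise NonConvergentEquilibriumError(
            "unit-pool calibration requires ke0 > 0 and kdeg > 0")
    return ke0 * kdeg / (kr + kdeg)


def default_params(r_scale: float = 1.0, **overrides) -> ReceptorModelParams:
    """The packaged default parameter set.

    vs is chosen so that the ligand-free steady-state surface pool equals 1
    (at r_scale = 1); pass ``vs=...`` to override.
    """
    p = ReceptorModelParams(r_scale=r_scale, **overrides)
    if "vs" not in overrides:
        p = replace(p, vs=synthesis_rate_for_unit_pool(p.ke0, p.kr, p.kdeg))
    return p


@dataclass(frozen=True)
class ModelState:
    """Concentrations of the five receptor pools (receptor units)."""

    Rs: float
    Cs: float = 0.0
    Ps: float = 0.0
    Pi: float = 0.0
    Ri: float = 0.0

    def __post_init__(self):
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """One simulation: a time grid (minutes) and the state at each point."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 5), columns in SPECIES order
    ligand: LigandSpec
    params: ReceptorModelParams

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        if self.states.shape != (self.times.size, len(SPECIES)):
            raise ValueError("states must be (n_times, 5)")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_min": self.times}
        cols.update({s: self.species(s) for s in SPECIES})
        return pd.DataFrame(cols)


def initial_steady_state(params: ReceptorModelParams) -> ModelState:
    """Ligand-free steady state, emulating growth-factor deprivation.

    With no ligand the complexes vanish and (Rs, Ri) solve the linear balance

        vs - ke0*Rs + kr*Ri = 0
        ke0*Rs - (kr + kdeg)*Ri = 0

    after which the pools are multiplied by ``r_scale``.  With vs = 0 the
    system is closed and any pool size is stationary only in the absence of
    turnover; by convention the closed pool is initialized at the unit surface
    pool (Rs = r_scale, Ri = 0).
    """
    if params.vs == 0.0:
        return ModelState(Rs=params.r_scale, Ri=0.0)
    if params.kdeg <= 0 or params.ke0 <= 0:
        raise NonConvergentEquilibriumError(
            "vs > 0 requires ke0 > 0 and kdeg > 0 for a finite steady state")
    ri = params.vs / params.kdeg
    rs = (params.vs + params.kr * ri) / params.ke0
    return ModelState(Rs=rs * params.r_scale, Ri=ri * params.r_scale)


def _rhs(t, y, p: ReceptorModelParams, L: float, koff: float):
    Rs, Cs, Ps, Pi, Ri = y
    bind = p.kon * L * Rs
    dRs = p.vs - bind + koff * Cs - p.ke0 * Rs + p.kr * Ri
    dCs = bind - koff * Cs - p.kp * Cs + p.kdp * Ps
    dPs = p.kp * Cs - p.kdp * Ps - p.ke1 * Ps
    dPi = p.ke1 * Ps - p.kdpi * Pi - p.kdegP * Pi
    dRi = p.ke0 * Rs + p.kdpi * Pi - p.kr * Ri - p.kdeg * Ri
    return (dRs, dCs, dPs, dPi, dRi)


def simulate(
    params: ReceptorModelParams,
    ligand: LigandSpec,
    times,
    init: ModelState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model on a strictly increasing minute grid starting at 0.

    ``init`` defaults to the ligand-free steady state.  Uses a stiff-capable
    integrator (LSODA): binding equilibrates in minutes while trafficking acts
    over hours.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or times[0] != 0.0:
        raise ValueError("times must be a 1-D grid starting at 0")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if init is None:
        init = initial_steady_state(params)

    koff = params.koff(ligand)
    sol = solve_ivp(
        _rhs,
        (0.0, float(times[-1])),
        init.as_array(),
        method="LSODA",
        t_eval=times,
        args=(params, ligand.concentration, koff),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}")
    states = sol.y.T.copy()
    worst = states.min()
    if worst < -_NEG_TOL:
        i, _ = np.unravel_index(np.argmin(states), states.shape)
        raise IntegrationError(
            f"negative state {worst:.3e} at t = {times[i]:g} min",
            time=float(times[i]),
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=times, states=states, ligand=ligand, params=params)


def readout(traj: Trajectory, kind: str) -> np.ndarray:
    """Scalar time course summing the pools a given assay reports."""
    try:
        pools = READOUT_KINDS[kind]
    except KeyError:
        raise InvalidReadoutError(
            f"unknown readout {kind!r}; choose from {sorted(READOUT_KINDS)}"
        ) from None
    return sum(traj.species(s) for s in pools)
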