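"""Kinetic feasibility model of the cytosolic serine→glycine one-carbon cycle.

The crowding FBA predicts formate–tetrahydrofolate ligase (FTHFL) running
in reverse (10-formyl-THF + ADP + Pi → formate + THF + ATP) as a major ATP
source, but all four cycle reactions are annotated reversible, so the
direction must be checked kinetically.  This module builds an ODE model of
the four cytosolic enzymes

    SHMT :  ser + thf  ⇌  gly + mlthf (+ H2O)
    MTHFD:  mlthf + NADP+ ⇌ methf + NADPH
    MTHFC:  methf (+ H2O) ⇌ 10fthf (+ H+)
    FTHFL:  10fthf + ADP + Pi ⇌ formate + thf + ATP

with reversible Michaelis–Menten (convenience) rate laws, a constant serine
inflow and first-order glycine/formate drains, holding ATP/ADP/Pi/NADP(H)
as fixed cellular pools.  The folate moiety (thf + mlthf + methf + 10fthf)
is conserved by construction.  Concentrations in mM, time in minutes.

Rate constants follow the scale of published folate-cycle kinetic models;
the model's contract is qualitative: a stable steady state exists with
FTHFL running in the ATP-forming direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "SPECIES", "FOLATE_SPECIES", "RateLaw", "CycleModel", "StabilityReport",
    "default_rate_laws", "default_fixed_pools", "build_cycle_model",
    "find_steady_state", "assess_stability",
]

SPECIES = ("ser", "gly", "thf", "mlthf", "methf", "f10thf", "formate")
FOLATE_SPECIES = ("thf", "mlthf", "methf", "f10thf")
_IDX = {s: i for i, s in enumerate(SPECIES)}


@dataclass
class RateLaw:
    """Reversible Michaelis–Menten (convenience) kinetics.

    v = (Vf·Π_s S/Km_s − Vr·Π_p P/Km_p) /
        (Π_s(1+S/Km_s) + Π_p(1+P/Km_p) − 1)

    ``substrates``/``products`` map species name → Km (mM); species not in
    the dynamic state are looked up in the fixed pools.
    """

    name: str
    vmax_f: float  # mM/min
    vmax_r: float  # mM/min
    substrates: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)

    def rate(self, conc: dict[str, float]) -> float:
        num_f, den_s = self.vmax_f, 1.0
        for sp, km in self.substrates.items():
            x = max(conc[sp], 0.0) / km
            num_f *= x
            den_s *= 1.0 + x
        num_r, den_p = self.vmax_r, 1.0
        for sp, km in self.products.items():
            x = max(conc[sp], 0.0) / km
            num_r *= x
            den_p *= 1.0 + x
        return (num_f - num_r) / (den_s + den_p - 1.0)


def default_fixed_pools() -> dict[str, float]:
    """Chemostatted cofactor pools (mM): energy charge and NADPH poise of a
    proliferating mammalian cell."""
    return {"atp": 3.0, "adp": 0.3, "pi": 2.5, "nadp": 0.002, "nadph": 0.02}


def default_rate_laws() -> list[RateLaw]:
    """Cycle enzymes, written in the direction the ATP-forming loop runs."""
    return [
        RateLaw("SHMT", vmax_f=2.0, vmax_r=2.0,
                substrates={"ser": 0.6, "thf": 0.01},
                products={"gly": 3.0, "mlthf": 0.01}),
        RateLaw("MTHFD", vmax_f=5.0, vmax_r=1.0,
                substrates={"mlthf": 0.002, "nadp": 0.0005},
                products={"methf": 0.01, "nadph": 0.01}),
        RateLaw("MTHFC", vmax_f=10.0, vmax_r=2.0,
                substrates={"methf": 0.01},
                products={"f10thf": 0.05}),
        RateLaw("FTHFL", vmax_f=3.0, vmax_r=3.0,
                substrates={"f10thf": 0.005, "adp": 0.1, "pi": 1.0},
                products={"formate": 5.0, "thf": 0.03, "atp": 0.1}),
    ]


@dataclass
class CycleModel:
    rate_laws: list[RateLaw]
    fixed_pools: dict[str, float]
    serine_inflow: float = 0.05   # mM/min
    k_gly_out: float = 0.1        # 1/min
    k_formate_out: float = 0.5    # 1/min

    def __post_init__(self) -> None:
        self._laws = {law.name: law for law in self.rate_laws}
        for name in ("SHMT", "MTHFD", "MTHFC", "FTHFL"):
            if name not in self._laws:
                raise ValueError(f"missing rate law {name}")

    def _conc(self, y: np.ndarray) -> dict[str, float]:
        conc = dict(self.fixed_pools)
        conc.update({sp: float(y[i]) for sp, i in _IDX.items()})
        return conc

    def fluxes(self, y: np.ndarray) -> dict[str, float]:
        conc = self._conc(y)
        return {name: law.rate(conc) for name, law in self._laws.items()}

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        v = self.fluxes(y)
        d = np.zeros(len(SPECIES))
        d[_IDX["ser"]] = self.serine_inflow - v["SHMT"]
        d[_IDX["gly"]] = v["SHMT"] - self.k_gly_out * y[_IDX["gly"]]
        d[_IDX["thf"]] = v["FTHFL"] - v["SHMT"]
        d[_IDX["mlthf"]] = v["SHMT"] - v["MTHFD"]
        d[_IDX["methf"]] = v["MTHFD"] - v["MTHFC"]
        d[_IDX["f10thf"]] = v["MTHFC"] - v["FTHFL"]
        d[_IDX["formate"]] = v["FTHFL"] - self.k_formate_out * y[_IDX["formate"]]
        return d

    def total_folate(self, y: np.ndarray) -> float:
        return float(sum(y[_IDX[s]] for s in FOLATE_SPECIES))

    def default_initial_state(self) -> np.ndarray:
        y0 = np.zeros(len(SPECIES))
        y0[_IDX["ser"]] = 0.5
        y0[_IDX["gly"]] = 1.0
        y0[_IDX["thf"]] = 0.020
        y0[_IDX["mlthf"]] = 0.005
        y0[_IDX["methf"]] = 0.002
        y0[_IDX["f10thf"]] = 0.003
        y0[_IDX["formate"]] = 0.01
        return y0


def build_cycle_model(rate_laws: list[RateLaw] | None = None,
                      fixed_pools: dict[str, float] | None = None,
                      **boundary) -> CycleModel:
    return CycleModel(rate_laws or default_rate_laws(),
                      fixed_pools or default_fixed_pools(), **boundary)


def find_steady_state(model: CycleModel,
                      initial_state: np.ndarray | None = None,
                      t_relax: float = 5000.0,
                      tol: float = 1e-10) -> np.ndarray | None:
    """Integrate to near-equilibration, then polish with a root solve.

    The folate conservation law is eliminated before root-finding (thf is
    expressed through the conserved total), so the reduced Jacobian is
    non-singular.  Returns the state, or None if no steady state is reached
    (divergence is reported, not raised).
    """
    y0 = model.default_initial_state() if initial_state is None \
        else np.asarray(initial_state, dtype=float)
    folate_total = model.total_folate(y0)

    sol = solve_ivp(model.rhs, (0.0, t_relax), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        return None
    y_relaxed = sol.y[:, -1]

    free = [s for s in SPECIES if s != "thf"]

    def expand(z: np.ndarray) -> np.ndarray:
        y = np.zeros(len(SPECIES))
        for s, v in zip(free, z):
            y[_IDX[s]] = v
        y[_IDX["thf"]] = folate_total - sum(
            y[_IDX[s]] for s in FOLATE_SPECIES if s != "thf")
        return y

    def reduced(z: np.ndarray) -> np.ndarray:
        d = model.rhs(0.0, expand(z))
        return np.array([d[_IDX[s]] for s in free])

    z0 = np.array([y_relaxed[_IDX[s]] for s in free])
    res = root(reduced, z0, method="hybr", tol=1e-14)
    y_ss = expand(res.x)
    scale = max(1.0, float(np.max(np.abs(y_ss))))
    if not res.success or np.any(y_ss < -1e-12) \
            or np.max(np.abs(model.rhs(0.0, y_ss))) > tol * scale:
        return None
    return np.clip(y_ss, 0.0, None)


@dataclass
class StabilityReport:
    eigenvalues: np.ndarray
    conservation_index: int
    max_real_part: float  # over non-conservation modes

    @property
    def stable(self) -> bool:
        return self.max_real_part < 0.0


def numerical_jacobian(model: CycleModel, y: np.ndarray,
                       eps: float = 1e-8) -> np.ndarray:
    n = len(y)
    J = np.zeros((n, n))
    for j in range(n):
        h = eps * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (model.rhs(0.0, yp) - model.rhs(0.0, ym)) / (2 * h)
    return J


def assess_stability(model: CycleModel, state: np.ndarray) -> StabilityReport:
    """Eigenvalues of the Jacobian at a steady state.

    The folate conservation law contributes one structurally zero
    eigenvalue; it is identified (smallest |λ|) and excluded, and the state
    is stable iff every remaining eigenvalue has negative real part.
    """
    J = numerical_jacobian(model, np.asarray(state, dtype=float))
    eig = np.linalg.eigvals(J)
    cons = int(np.argmin(np.abs(eig)))
    rest = np.delete(eig, cons)
    return StabilityReport(eig, cons, float(np.max(rest.real)))
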