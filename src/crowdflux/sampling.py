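"""Monte-Carlo sampling of effective turnover numbers.

Enzyme turnover numbers measured in humans span roughly 1–100 s⁻¹ with
log10(k) close to uniform, so unknown k_eff values are drawn i.i.d. from a
log10-uniform distribution on that range, one draw per irreversible
reaction direction.  An ensemble of draws is solved and summarised by the
median and the empirical 5th/95th percentiles (90% confidence band).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .biophysics import BiophysicalParams
from .fba import FluxSolution, solve
from .network import Network

__all__ = ["KeffAssignment", "Ensemble", "sample_keff", "apply_keff",
           "run_ensemble", "aggregate"]


@dataclass
class KeffAssignment:
    values: dict[str, float]  # reaction id -> k_eff, 1/min
    seed: int

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]


def _enzymatic_ids(net: Network) -> list[str]:
    return [r.id for r in net.reactions if r.is_enzymatic]


def sample_keff(net: Network, seed: int,
                keff_range: tuple[float, float] = (60.0, 6000.0)
                ) -> KeffAssignment:
    """Draw one k_eff per enzymatic irreversible reaction (1/min).

    log10(k_eff in s⁻¹) ~ Uniform[log10(lo/60), log10(hi/60)]; forward and
    backward copies of a split reversible reaction are independent draws.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = keff_range
    ids = _enzymatic_ids(net)
    exponents = rng.uniform(math.log10(lo), math.log10(hi), size=len(ids))
    return KeffAssignment({rid: 10.0 ** e for rid, e in zip(ids, exponents)},
                          seed=seed)


def apply_keff(net: Network, assignment: KeffAssignment) -> Network:
    net = net.copy()
    for rid, k in assignment.values.items():
        net.rxn_index[rid].keff = k
    return net


@dataclass
class Ensemble:
    replicates: list[FluxSolution]
    assignments: list[KeffAssignment]
    n_requested: int
    n_infeasible: int
    base_seed: int

    @property
    def solutions(self) -> list[FluxSolution]:
        return [s for s in self.replicates if s.optimal]

    def manifest(self) -> dict:
        return {
            "base_seed": self.base_seed,
            "n_requested": self.n_requested,
            "n_infeasible": self.n_infeasible,
            "replicate_seeds": [a.seed for a in self.assignments],
        }


def run_ensemble(net: Network, params: BiophysicalParams, mu_per_day: float,
                 n: int = 100, base_seed: int = 0,
                 max_infeasible_fraction: float = 0.1) -> Ensemble:
    """Solve ``n`` replicates with independently sampled k_eff.

    Replicate r uses seed base_seed + r.  Infeasible replicates are kept in
    ``replicates`` (for the record) but excluded from quantiles; more than
    ``max_infeasible_fraction`` of them is an error.
    """
    replicates, assignments = [], []
    for r in range(n):
        assignment = sample_keff(net, base_seed + r, params.keff_range)
        assignments.append(assignment)
        replicates.append(solve(apply_keff(net, assignment), params,
                                mu_per_day))
    n_bad = sum(not s.optimal for s in replicates)
    if n > 0 and n_bad > max_infeasible_fraction * n:
        raise RuntimeError(
            f"{n_bad}/{n} replicates infeasible at mu={mu_per_day}/day")
    return Ensemble(replicates, assignments, n, n_bad, base_seed)


def aggregate(ensemble: Ensemble,
              extractor: Callable[[FluxSolution], float]
              ) -> tuple[float, float, float]:
    """(median, 5th, 95th percentile) of a scalar across feasible replicates.

    Quantiles use linear (type-7) interpolation for cross-language
    comparability.
    """
    vals = np.array([extractor(s) for s in ensemble.solutions], dtype=float)
    if vals.size == 0:
        raise ValueError("no feasible replicates to aggregate")
    med, lo, hi = np.percentile(vals, [50, 5, 95], method="linear")
    return float(med), float(lo), float(hi)
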