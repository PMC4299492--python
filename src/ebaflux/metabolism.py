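"""Metabolic layer: FBA/FVA linear programs and expression-gated flux bounds.

FBA maximizes an objective flux subject to steady-state mass balance
``S v = 0`` and per-reaction bounds; FVA reports each reaction's feasible
flux range, optionally conditioned on a fraction of optimal biomass.  The
expression gating rescales FVA-derived bound magnitudes by each
reaction's enzyme activity ratio: per enzyme gene the ratio is 1 while the
predicted expression stays within ``n`` wild-type standard deviations of
the wild-type mean, and the log2 fold change ``2**(y_hat - y_wt)``
otherwise; GPR trees combine gene ratios (AND -> min, OR -> max) and the
resulting P-function is capped at ``p_cap``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from ._gpr import GPRNode
from .io import MetabolicModelFile
from .signals import SignalSystem
from .transcriptional import RegulatoryModel

_TOL = 1e-9
ESSENTIALITY_GROWTH_FRACTION = 0.05


@dataclass
class FluxBounds:
    """Per-reaction (v_min, v_max) pairs."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for rxn, (lo, hi) in self.bounds.items():
            if lo > hi + _TOL:
                raise ValueError(f"reaction {rxn!r}: v_min {lo} > v_max {hi}")

    @classmethod
    def from_model(cls, model: MetabolicModelFile) -> "FluxBounds":
        return cls({r.id: (r.lower_bound, r.upper_bound)
                    for r in model.reactions})

    def __getitem__(self, rxn: str) -> tuple[float, float]:
        return self.bounds[rxn]

    def with_overrides(
        self, overrides: Iterable[tuple[str, float, float]]
    ) -> "FluxBounds":
        out = dict(self.bounds)
        for rxn, lo, hi in overrides:
            if rxn not in out:
                raise KeyError(f"unknown reaction {rxn!r} in override")
            out[rxn] = (float(lo), float(hi))
        return FluxBounds(out)


@dataclass
class FluxState:
    v: dict[str, float]
    growth: float | None
    status: str                      # "optimal" | "infeasible"
    objective_reaction: str = ""


@dataclass
class TrameParams:
    """Gating parameters: gate width ``n`` (WT sd units) and P-function cap."""

    n: float = 2.0
    p_cap: float = 10.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.p_cap < 1:
            raise ValueError("p_cap must be >= 1")


def _lp_arrays(model: MetabolicModelFile, bounds: FluxBounds):
    S = model.stoichiometric_matrix()
    lp_bounds = [bounds[r.id] for r in model.reactions]
    return S, lp_bounds


def _solve_lp(model: MetabolicModelFile, bounds: FluxBounds, c: np.ndarray,
              extra_A_ub=None, extra_b_ub=None):
    S, lp_bounds = _lp_arrays(model, bounds)
    res = linprog(
        c,
        A_eq=S, b_eq=np.zeros(S.shape[0]),
        A_ub=extra_A_ub, b_ub=extra_b_ub,
        bounds=lp_bounds,
        method="highs",
    )
    return res


def fba(model: MetabolicModelFile, bounds: FluxBounds | None = None,
        objective: str | None = None) -> FluxState:
    """Maximize an objective flux (default: biomass) under mass balance."""
    if bounds is None:
        bounds = FluxBounds.from_model(model)
    obj = objective if objective is not None else model.biomass_reaction_id
    try:
        j = model._rxn_index[obj]
    except KeyError:
        raise KeyError(f"objective reaction {obj!r} not in model") from None
    c = np.zeros(model.n_reactions)
    c[j] = -1.0  # linprog minimizes
    res = _solve_lp(model, bounds, c)
    if not res.success:
        return FluxState(v={}, growth=None, status="infeasible",
                         objective_reaction=obj)
    v = {r.id: float(res.x[k]) for k, r in enumerate(model.reactions)}
    return FluxState(v=v, growth=float(res.x[j]), status="optimal",
                     objective_reaction=obj)


def fva(model: MetabolicModelFile, bounds: FluxBounds | None = None,
        biomass_fraction: float = 0.0) -> FluxBounds:
    """Per-reaction flux ranges, optionally at >= fraction of optimal biomass.

    ``biomass_fraction=0`` yields the full physically feasible envelope,
    which is what the expression gating consumes by default.
    """
    if not 0.0 <= biomass_fraction <= 1.0:
        raise ValueError("biomass_fraction must be in [0, 1]")
    if bounds is None:
        bounds = FluxBounds.from_model(model)
    extra_A, extra_b = None, None
    if biomass_fraction > 0:
        wt = fba(model, bounds)
        if wt.status != "optimal":
            raise RuntimeError("model infeasible; cannot run FVA")
        row = np.zeros(model.n_reactions)
        row[model._rxn_index[model.biomass_reaction_id]] = -1.0
        extra_A = row.reshape(1, -1)
        extra_b = np.array([-biomass_fraction * wt.growth])
    out: dict[str, tuple[float, float]] = {}
    for j, r in enumerate(model.reactions):
        c = np.zeros(model.n_reactions)
        c[j] = 1.0
        lo_res = _solve_lp(model, bounds, c, extra_A, extra_b)
        c[j] = -1.0
        hi_res = _solve_lp(model, bounds, c, extra_A, extra_b)
        if not (lo_res.success and hi_res.success):
            raise RuntimeError(
                f"FVA subproblem infeasible for reaction {r.id!r}"
            )
        lo, hi = float(lo_res.x[j]), float(hi_res.x[j])
        if lo > hi:  # numerical jitter on a point range
            lo = hi = (lo + hi) / 2.0
        out[r.id] = (lo, hi)
    return FluxBounds(out)


def reaction_activity(gpr: GPRNode | None, rel_expr: Mapping[str, float],
                      or_mode: str = "max") -> float:
    """Combine per-gene activity ratios through a GPR tree.

    AND takes the limiting (minimum) subunit; OR takes the best isozyme
    (``max``; ``or_mode="sum"`` pools isozyme capacity instead).  Genes
    without a ratio default to 1 (unchanged).  A reaction without a GPR
    has activity 1.
    """
    if gpr is None:
        return 1.0
    return max(0.0, gpr.evaluate(rel_expr, default=1.0, or_mode=or_mode))


def expression_ratios(y_hat: np.ndarray | Mapping[str, float],
                      reg_model: RegulatoryModel,
                      params: TrameParams,
                      zero_genes: Iterable[str] = ()) -> dict[str, float]:
    """Per-gene activity ratios relative to wild type, gated by WT variability.

    Within ``n * sigma_wt`` of the WT mean the ratio is exactly 1; outside
    the gate it is the fold change ``2**(y_hat - y_wt)``.  Genes in
    ``zero_genes`` (hard knockouts) get ratio 0 regardless of expression.
    """
    if isinstance(y_hat, Mapping):
        y = np.array([y_hat[g] for g in reg_model.genes], dtype=float)
    else:
        y = np.asarray(y_hat, dtype=float)
        if y.shape != (reg_model.n_genes,):
            raise ValueError("y_hat length does not match model genes")
    delta = y - reg_model.y_wt
    if np.isinf(params.n):  # limit case: everything inside the gate
        gated = np.ones_like(delta, dtype=bool)
    else:
        gated = np.abs(delta) <= params.n * reg_model.sigma_wt
    rho = np.where(gated, 1.0, np.exp2(delta))
    ratios = {g: float(r) for g, r in zip(reg_model.genes, rho)}
    for g in zero_genes:
        ratios[g] = 0.0
    return ratios


def trame_bounds(fva_bounds: FluxBounds, model: MetabolicModelFile,
                 y_hat: np.ndarray | Mapping[str, float],
                 reg_model: RegulatoryModel,
                 params: TrameParams | None = None,
                 zero_genes: Iterable[str] = (),
                 or_mode: str = "max") -> FluxBounds:
    """Rescale FVA bound magnitudes by GPR-combined expression ratios.

    For each reaction with a GPR, the P-function ``min(activity, p_cap)``
    multiplies the positive part of v_max and the negative part of v_min:
    magnitudes scale, signs are preserved, and reactions without a GPR are
    untouched.
    """
    if params is None:
        params = TrameParams()
    rho = expression_ratios(y_hat, reg_model, params, zero_genes)
    out: dict[str, tuple[float, float]] = {}
    for r in model.reactions:
        lo, hi = fva_bounds[r.id]
        if r.gpr is not None:
            p = min(reaction_activity(r.gpr, rho, or_mode), params.p_cap)
            if hi > 0:
                hi = hi * p
            if lo < 0:
                lo = lo * p
        out[r.id] = (lo, hi)
    return FluxBounds(out)


def essentiality(
    met_model: MetabolicModelFile,
    reg_model: RegulatoryModel,
    system: SignalSystem | None,
    gene: str,
    environment: Sequence[tuple[str, float]] = (),
    exchange_overrides: Sequence[tuple[str, float, float]] = (),
    params: TrameParams | None = None,
    gamma: float = 0.0,
    hard_gpr_knockout: bool = True,
) -> str:
    """Classify a gene knockout as ``essential`` or ``non_essential``.

    Runs the full expression -> flux-gating -> growth pipeline with the
    gene knocked out and compares predicted growth to the wild type in the
    same environment; growth below 5% of wild type (or infeasibility) is
    essential.  A gene appearing only in GPRs (no regulatory equation) is
    evaluated by zeroing its enzyme activity directly.
    """
    from .eba import PerturbationScenario
    from .integration import predict_growth

    in_reg = reg_model.has_gene(gene)
    in_gpr = any(r.gpr is not None and gene in r.gpr.genes()
                 for r in met_model.reactions)
    if not (in_reg or in_gpr):
        raise KeyError(
            f"gene {gene!r} is in neither the regulatory model nor any GPR"
        )
    if params is None:
        params = TrameParams()

    if in_reg:
        ko = PerturbationScenario(
            knockouts=[gene], environment=list(environment),
            exchange_overrides=list(exchange_overrides),
        )
        wt = PerturbationScenario(
            environment=list(environment),
            exchange_overrides=list(exchange_overrides),
        )
        pred_ko = predict_growth(reg_model, system, met_model, ko,
                                 params=params, gamma=gamma,
                                 hard_gpr_knockout=hard_gpr_knockout)
        pred_wt = predict_growth(reg_model, system, met_model, wt,
                                 params=params, gamma=gamma,
                                 hard_gpr_knockout=hard_gpr_knockout)
        if pred_wt.mu <= 0:
            return "essential" if pred_ko.mu <= 0 else "non_essential"
        rel = pred_ko.mu / pred_wt.mu
    else:
        # enzyme-only gene: zero its activity in the GPR layer
        envelope = fva(met_model)
        ref = fba(met_model, FluxBounds.from_model(met_model)
                  .with_overrides(exchange_overrides))
        if ref.status != "optimal" or not ref.growth or ref.growth <= 0:
            raise RuntimeError("wild-type model has no positive growth")
        gated = trame_bounds(envelope, met_model, reg_model.y_wt, reg_model,
                             params, zero_genes=[gene])
        state = fba(met_model, gated.with_overrides(exchange_overrides))
        if state.status != "optimal":
            return "essential"
        rel = (state.growth or 0.0) / ref.growth
    return ("essential" if rel < ESSENTIALITY_GROWTH_FRACTION
            else "non_essential")
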