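"""Cost-benefit integration of the expression and metabolic layers.

Predicted relative growth is ``mu = max(0, B - c)`` where the metabolic
benefit ``B`` is the FBA growth under expression-gated flux bounds
normalized by the wild-type reference growth, and the expression cost
``c`` is the mean per-gene expression deviation from the wild-type
profile, normalized by each gene's dynamic range and scaled by ``gamma``.
All quantities are relative (wild type = 1), so benefit and cost are
commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .eba import EBAResult, PerturbationScenario, predict_expression
from .io import MetabolicModelFile
from .metabolism import (FluxBounds, FluxState, TrameParams, fba, fva,
                         trame_bounds)
from .signals import SignalSystem
from .transcriptional import RegulatoryModel


@dataclass
class GrowthPrediction:
    benefit: float                     # B, wild type = 1
    cost: float                        # c >= 0
    mu: float                          # max(0, B - c)
    y_hat: np.ndarray
    fluxes: FluxState | None
    diagnostics: dict = field(default_factory=dict)


def expression_cost(y_hat: np.ndarray, reg_model: RegulatoryModel,
                    gamma: float = 1.0,
                    y_ref: np.ndarray | None = None) -> float:
    """Range-normalized mean absolute expression deviation, scaled by gamma.

    ``c = gamma / N * sum_i |y_hat_i - y_ref_i| / (y_max_i - y_min_i)``
    with ``y_ref`` defaulting to the wild-type mean profile.  Genes with
    zero dynamic range are skipped (and N decremented): they cannot
    deviate in relative terms.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if gamma == 0:
        return 0.0
    ref = reg_model.y_wt if y_ref is None else np.asarray(y_ref, dtype=float)
    y = np.asarray(y_hat, dtype=float)
    span = reg_model.y_max - reg_model.y_min
    ok = span > 0
    n_eff = int(ok.sum())
    if n_eff == 0:
        return 0.0
    dev = np.abs(y[ok] - ref[ok]) / span[ok]
    return float(gamma * dev.sum() / n_eff)


def metabolic_benefit(
    model: MetabolicModelFile,
    bounds_after_gating: FluxBounds,
    exchange_overrides: Sequence[tuple[str, float, float]] = (),
    reference_bounds: FluxBounds | None = None,
) -> float:
    """Perturbed FBA growth relative to the reference (wild-type) growth.

    The reference defaults to the model's native bounds.  An infeasible
    perturbed model yields benefit 0.
    """
    if reference_bounds is None:
        reference_bounds = FluxBounds.from_model(model)
    ref = fba(model, reference_bounds)
    if ref.status != "optimal" or ref.growth is None or ref.growth <= 0:
        raise RuntimeError("reference model has no positive growth")
    try:
        perturbed_bounds = bounds_after_gating.with_overrides(exchange_overrides)
    except ValueError:
        return 0.0  # overrides produced an empty box
    state = fba(model, perturbed_bounds)
    if state.status != "optimal" or state.growth is None:
        return 0.0
    return max(0.0, float(state.growth) / float(ref.growth))


def predict_growth(
    reg_model: RegulatoryModel,
    system: SignalSystem | None,
    met_model: MetabolicModelFile,
    scenario: PerturbationScenario,
    params: TrameParams | None = None,
    gamma: float = 1.0,
    H: np.ndarray | None = None,
    tolerance: float = 1e-8,
    hard_knockout: bool = False,
    hard_gpr_knockout: bool = True,
    biomass_fraction: float = 0.0,
) -> GrowthPrediction:
    """Full pipeline: expression QP -> flux-bound gating -> FBA -> cost-benefit.

    Both the cost and the benefit are measured against the pipeline's own
    wild-type run (empty genetic scenario, reference environment), so the
    wild-type scenario is exactly ``B = 1, c = 0, mu = 1``.  With
    ``hard_gpr_knockout`` knocked-out genes additionally have their enzyme
    activity zeroed in the GPR layer (a deleted gene makes no protein even
    if its capacity floor is above zero expression).
    """
    if params is None:
        params = TrameParams()

    def _run(scn: PerturbationScenario) -> tuple[EBAResult, FluxState]:
        eba_res = predict_expression(reg_model, system, scn, H=H,
                                     tolerance=tolerance,
                                     hard_knockout=hard_knockout)
        envelope = fva(met_model, biomass_fraction=biomass_fraction)
        zero = scn.knockouts if hard_gpr_knockout else ()
        gated = trame_bounds(envelope, met_model, eba_res.y_hat, reg_model,
                             params, zero_genes=zero)
        try:
            final = gated.with_overrides(scn.exchange_overrides)
        except ValueError:
            return eba_res, FluxState(v={}, growth=None, status="infeasible")
        return eba_res, fba(met_model, final)

    wt_scenario = PerturbationScenario()
    eba_wt, flux_wt = _run(wt_scenario)
    if flux_wt.status != "optimal" or not flux_wt.growth or flux_wt.growth <= 0:
        raise RuntimeError("wild-type pipeline run has no positive growth")

    eba_res, flux = _run(scenario)
    if flux.status != "optimal" or flux.growth is None:
        benefit = 0.0
    else:
        benefit = max(0.0, float(flux.growth) / float(flux_wt.growth))
    cost = expression_cost(eba_res.y_hat, reg_model, gamma=gamma,
                           y_ref=eba_wt.y_hat)
    mu = max(0.0, benefit - cost)

    return GrowthPrediction(
        benefit=benefit,
        cost=cost,
        mu=mu,
        y_hat=eba_res.y_hat,
        fluxes=flux,
        diagnostics={
            "eba_status": eba_res.status,
            "eba_objective": eba_res.objective,
            "eba_relaxation": eba_res.relaxation,
            "flux_status": flux.status,
            "wt_growth": float(flux_wt.growth),
            "negative_fitness_floored": benefit - cost < 0,
        },
    )
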