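"""Expression balance analysis: perturbation-response expression prediction.

Given a trained linear transcriptional model and a perturbation scenario,
the predicted genome-wide profile solves a convex quadratic program on the
TF subnetwork.  Each TF equation carries a slack

    epsilon_j = y_j - beta0_j - sum_k beta_jk * y_k     (k over TFs)

and the objective minimizes ``epsilon' H epsilon`` subject to four
constraint families: the linear model equations themselves
(phenomenological), per-gene capacity bounds ``y_min <= y <= y_max``,
environmental TF fixings from the signal layer, and genetic fixings
(knockout -> floor, over-expression -> ceiling, rewiring -> coefficient
swap).  Because the slacks are affine in the TF expressions, the QP is
solved as a box-constrained least-squares problem.  Non-TF genes are then
set by linear propagation from the solved TF profile, clamped to their
capacity bounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .signals import SignalSystem, environment_to_constraints
from .transcriptional import RegulatoryModel


class ScenarioError(ValueError):
    pass


@dataclass
class PerturbationScenario:
    """Genetic edits plus environment for one prediction run."""

    knockouts: list[str] = field(default_factory=list)
    overexpressions: list[str] = field(default_factory=list)
    rewirings: list[tuple[str, str]] = field(default_factory=list)  # (target, donor)
    environment: list[tuple[str, float]] = field(default_factory=list)
    exchange_overrides: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cats = {
            "knockout": set(self.knockouts),
            "overexpression": set(self.overexpressions),
            "rewiring": {t for t, _ in self.rewirings},
        }
        names = list(cats)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                both = cats[a] & cats[b]
                if both:
                    raise ScenarioError(
                        f"gene(s) {sorted(both)} appear in both {a} and {b}"
                    )
        for t, d in self.rewirings:
            if t == d:
                raise ScenarioError(f"rewiring donor equals target: {t!r}")

    @property
    def is_wild_type(self) -> bool:
        return not (self.knockouts or self.overexpressions or self.rewirings
                    or self.environment or self.exchange_overrides)

    def genetic_genes(self) -> set[str]:
        return (set(self.knockouts) | set(self.overexpressions)
                | {t for t, _ in self.rewirings})

    def to_dict(self) -> dict:
        return {
            "knockouts": list(self.knockouts),
            "overexpressions": list(self.overexpressions),
            "rewirings": [[t, d] for t, d in self.rewirings],
            "effectors": [{"id": e, "delta": d} for e, d in self.environment],
            "exchange_overrides": [[r, lb, ub]
                                   for r, lb, ub in self.exchange_overrides],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PerturbationScenario":
        return cls(
            knockouts=list(doc.get("knockouts", [])),
            overexpressions=list(doc.get("overexpressions", [])),
            rewirings=[(t, d) for t, d in doc.get("rewirings", [])],
            environment=[(e["id"], float(e["delta"]))
                         for e in doc.get("effectors", [])],
            exchange_overrides=[(r, float(lb), float(ub)) for r, lb, ub in
                                doc.get("exchange_overrides", [])],
        )

    def save(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "PerturbationScenario":
        with Path(path).open() as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class EBAResult:
    """Solved expression profile with TF slacks and solver diagnostics."""

    y_hat: np.ndarray                  # per-gene, aligned with model.genes
    epsilon: dict[str, float]          # per-TF equation slack
    objective: float                   # epsilon' H epsilon at the solution
    status: str                        # "optimal" | "infeasible_relaxed"
    relaxation: float = 0.0            # uniform bound slack applied, if any

    def profile(self, genes: Sequence[str]) -> dict[str, float]:
        return {g: float(v) for g, v in zip(genes, self.y_hat)}


def apply_scenario(
    model: RegulatoryModel,
    system: SignalSystem | None,
    scenario: PerturbationScenario,
    hard_knockout: bool = False,
) -> tuple[RegulatoryModel, dict[str, float]]:
    """Edit the model per the scenario; return (edited model, fixed map).

    Knockouts fix a gene at its capacity floor, over-expressions at its
    ceiling; a rewiring (target, donor) copies the donor's basal and
    regulatory coefficients onto the target.  Environmental effectors fix
    TF expressions and/or deactivate TFs via the signal layer; a
    deactivated TF's coefficient column is zeroed.  With ``hard_knockout``
    a knocked-out TF's column is zeroed as well (abolishing its regulatory
    output rather than pinning it at floor expression).
    """
    for g in scenario.genetic_genes():
        if not model.has_gene(g):
            raise ScenarioError(f"scenario gene {g!r} not in model")
    edited = model.copy()

    if scenario.rewirings:
        beta = edited.beta.tolil()
        for target, donor in scenario.rewirings:
            ti, di = edited.index(target), edited.index(donor)
            edited.beta0[ti] = edited.beta0[di]
            beta[ti, :] = beta[di, :]
        edited.beta = beta.tocsr()

    env_fixed: dict[str, float] = {}
    inactive: set[str] = set()
    if scenario.environment:
        if system is None:
            raise ScenarioError(
                "scenario has effectors but no signal system was supplied"
            )
        env_fixed, inactive = environment_to_constraints(
            system, edited, scenario.environment
        )

    fixed: dict[str, float] = {}
    sources: dict[str, str] = {}

    def _fix(gene: str, value: float, source: str) -> None:
        if gene in fixed and fixed[gene] != value:
            raise ScenarioError(
                f"conflicting fixed values for {gene!r}: "
                f"{fixed[gene]} from {sources[gene]} vs {value} from {source}"
            )
        fixed[gene] = value
        sources[gene] = source

    for g in scenario.knockouts:
        _fix(g, float(edited.y_min[edited.index(g)]), "knockout")
    for g in scenario.overexpressions:
        _fix(g, float(edited.y_max[edited.index(g)]), "overexpression")
    for tf, val in env_fixed.items():
        _fix(tf, val, "environment")

    zero_cols = set(inactive)
    if hard_knockout:
        zero_cols |= {g for g in scenario.knockouts if g in edited.tf_set}
    if zero_cols:
        beta = edited.beta.tolil()
        for tf in zero_cols:
            beta[:, edited.index(tf)] = 0.0
        edited.beta = beta.tocsr()

    return edited, fixed


def solve(model: RegulatoryModel, fixed: Mapping[str, float],
          H: np.ndarray | None = None, tolerance: float = 1e-8) -> EBAResult:
    """Solve the expression-balance QP for a (possibly edited) model.

    Stage 1 optimizes the unfixed TF expressions within their capacity
    bounds, minimizing the H-weighted sum of squared TF-equation slacks;
    stage 2 propagates the TF solution linearly to all non-TF genes and
    clamps them.  Fixed genes keep their fixed values verbatim.  Should the
    capacity box be empty (only possible after external bound edits), all
    unfixed-TF bounds are relaxed by the minimal uniform slack and the
    result is flagged ``infeasible_relaxed``.
    """
    tf_list = model.tf_list
    n_tf = len(tf_list)
    tf_idx = np.array([model.index(t) for t in tf_list], dtype=int)
    if H is None:
        H = np.eye(n_tf)
    else:
        H = np.asarray(H, dtype=float)
        if H.shape != (n_tf, n_tf):
            raise ValueError(f"H must be {n_tf}x{n_tf}")
    L = np.linalg.cholesky(H).T  # H = L'L

    for g, v in fixed.items():
        if not model.has_gene(g):
            raise ScenarioError(f"fixed gene {g!r} not in model")

    # TF-subnetwork coefficient block (rows and columns in tf_list order)
    B = model.beta[np.ix_(tf_idx, tf_idx)].toarray()
    beta0_tf = model.beta0[tf_idx]
    lb = model.y_min[tf_idx].copy()
    ub = model.y_max[tf_idx].copy()

    relaxation = 0.0
    status = "optimal"
    gap = lb - ub
    if np.any(gap > 0):
        relaxation = float(gap.max()) / 2.0 + tolerance
        lb = lb - relaxation
        ub = ub + relaxation
        status = "infeasible_relaxed"
        warnings.warn(
            f"empty capacity box; bounds relaxed uniformly by {relaxation:g}",
            stacklevel=2,
        )

    fixed_tf = {t: fixed[t] for t in tf_list if t in fixed}
    # degenerate bounds pin a TF as effectively fixed
    for a, t in enumerate(tf_list):
        if t not in fixed_tf and lb[a] == ub[a]:
            fixed_tf[t] = float(lb[a])
    free_pos = [a for a, t in enumerate(tf_list) if t not in fixed_tf]

    y_tf = np.zeros(n_tf)
    for a, t in enumerate(tf_list):
        if t in fixed_tf:
            y_tf[a] = fixed_tf[t]

    # epsilon = A x + c, x = y over free TFs
    if free_pos:
        A = np.zeros((n_tf, len(free_pos)))
        for p, a in enumerate(free_pos):
            A[:, p] = -B[:, a]
            A[a, p] += 1.0
        c = -beta0_tf.copy()
        fixed_mask = np.array([t in fixed_tf for t in tf_list])
        c += np.where(fixed_mask, y_tf, 0.0)
        c -= B[:, fixed_mask] @ y_tf[fixed_mask]
        res = lsq_linear(
            L @ A, -(L @ c),
            bounds=(lb[free_pos], ub[free_pos]),
            tol=tolerance, max_iter=500,
        )
        for p, a in enumerate(free_pos):
            y_tf[a] = res.x[p]

    eps = y_tf - beta0_tf - B @ y_tf
    objective = float(eps @ H @ eps)

    # stage 2: propagate to all genes, clamp, then restore TF/fixed values
    y_full_tf = np.zeros(model.n_genes)
    y_full_tf[tf_idx] = y_tf
    y_hat = model.clamp(model.beta0 + model.beta @ y_full_tf)
    y_hat[tf_idx] = y_tf
    for g, v in fixed.items():
        y_hat[model.index(g)] = v

    return EBAResult(
        y_hat=y_hat,
        epsilon={t: float(e) for t, e in zip(tf_list, eps)},
        objective=objective,
        status=status,
        relaxation=relaxation,
    )


def predict_expression(
    model: RegulatoryModel,
    system: SignalSystem | None,
    scenario: PerturbationScenario,
    H: np.ndarray | None = None,
    tolerance: float = 1e-8,
    hard_knockout: bool = False,
) -> EBAResult:
    """Apply a scenario and solve the expression-balance QP."""
    edited, fixed = apply_scenario(model, system, scenario,
                                   hard_knockout=hard_knockout)
    return solve(edited, fixed, H=H, tolerance=tolerance)
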