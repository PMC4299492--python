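"""Seeded generators for every input artifact, with recoverable ground truth.

The generators emit a scale-free signed regulatory network with known
coefficients, steady-state compendia with Gaussian noise, a toy chain
metabolic model wired to network genes, signal-transduction entries, and a
random term annotation — everything the framework consumes, so the whole
pipeline is testable without external downloads.

All randomness flows from one integer seed through named substreams
(``_rng(seed, stream)``), so each artifact regenerates independently yet
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from .eba import PerturbationScenario
from .io import (ArrayMeta, ExpressionTable, GoAnnotation, MetabolicModelFile,
                 NetworkEdge, NetworkTable, Reaction)
from .metabolism import FluxBounds, TrameParams, fba, fva
from .signals import SignalEntry, SignalSystem
from ._gpr import parse_gpr

EXPRESSION_FLOOR = 0.0
EXPRESSION_CEILING = 14.0
_SPECTRAL_RADIUS_CAP = 0.85

_STREAMS = {"trn": 0, "compendium": 1, "metabolic": 2, "sts": 3,
            "annotation": 4, "scenarios": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream]])
    )


@dataclass
class GroundTruth:
    """True generator parameters behind a synthetic regulatory network."""

    genes: list[str]
    tf_ids: list[str]
    beta0: np.ndarray
    beta: sparse.csr_matrix        # beta[i, j]: effect of gene j on gene i
    y_star: np.ndarray             # wild-type fixed point
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = sparse.csr_matrix(self.beta)
        self._index = {g: i for i, g in enumerate(self.genes)}

    def index(self, gene: str) -> int:
        return self._index[gene]

    def spectral_radius(self) -> float:
        tf_idx = [self._index[t] for t in self.tf_ids]
        sub = self.beta[np.ix_(tf_idx, tf_idx)].toarray()
        if sub.size == 0:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(sub))))


@dataclass
class MetabolicGroundTruth:
    optimal_growth: float
    essential_genes: set[str]
    isozyme_genes: set[str]
    step_genes: dict[str, list[str]]   # reaction id -> its GPR genes
    uptake_reaction: str


# ---------------------------------------------------------------------------
# Regulatory network


def generate_trn(n_genes: int, n_tfs: int, mean_out_degree: float,
                 p_activator: float = 0.6, seed: int = 0
                 ) -> tuple[NetworkTable, GroundTruth]:
    """Scale-free signed TRN with ground-truth linear coefficients.

    TF out-degrees grow by preferential attachment (heavy-tailed); edge
    signs are "+" with probability ``p_activator``; coefficient magnitudes
    are log-normal and globally rescaled so the TF-subnetwork spectral
    radius stays below 0.9 (a stable fixed point exists).  Basal
    coefficients are back-solved so the wild-type fixed point sits
    mid-range of the [0, 14] log2 scale.
    """
    if not 1 <= n_tfs < n_genes:
        raise ValueError("need 1 <= n_tfs < n_genes")
    if mean_out_degree < 1:
        raise ValueError("mean_out_degree must be >= 1")
    if not 0 <= p_activator <= 1:
        raise ValueError("p_activator must be in [0, 1]")
    rng = _rng(seed, "trn")
    genes = [f"g{i:04d}" for i in range(n_genes)]
    tf_ids = genes[:n_tfs]

    n_edges = int(round(mean_out_degree * n_tfs))
    out_degree = np.zeros(n_tfs)
    edges: set[tuple[int, int]] = set()
    max_possible = n_tfs * (n_genes - 1)
    attempts = 0
    while len(edges) < min(n_edges, max_possible) and attempts < 50 * n_edges:
        attempts += 1
        w = out_degree + 1.0
        tf = int(rng.choice(n_tfs, p=w / w.sum()))
        tgt = int(rng.integers(n_genes))
        if tgt == tf or (tf, tgt) in edges:
            continue
        edges.add((tf, tgt))
        out_degree[tf] += 1

    edge_list = sorted(edges)
    signs = np.where(rng.random(len(edge_list)) < p_activator, "+", "-")
    mags = rng.lognormal(mean=-1.0, sigma=0.5, size=len(edge_list))
    tiers = rng.choice(["confirmed", "strong", "weak", "inferred"],
                       size=len(edge_list), p=[0.3, 0.3, 0.25, 0.15])

    beta = sparse.lil_matrix((n_genes, n_genes))
    rows = []
    for (tf, tgt), s, m, tier in zip(edge_list, signs, mags, tiers):
        coef = m if s == "+" else -m
        beta[tgt, tf] = coef
        rows.append(NetworkEdge(genes[tf], genes[tgt], str(s), str(tier)))
    beta = beta.tocsr()

    sub = beta[:n_tfs, :n_tfs].toarray()
    rho = float(np.max(np.abs(np.linalg.eigvals(sub)))) if sub.size else 0.0
    if rho >= _SPECTRAL_RADIUS_CAP:
        beta = beta * (_SPECTRAL_RADIUS_CAP / rho)

    y_star = rng.uniform(4.0, 10.0, size=n_genes)
    beta0 = y_star - beta @ y_star

    truth = GroundTruth(
        genes=genes, tf_ids=tf_ids, beta0=beta0, beta=beta, y_star=y_star,
        config={"n_genes": n_genes, "n_tfs": n_tfs,
                "mean_out_degree": mean_out_degree,
                "p_activator": p_activator, "seed": int(seed)},
    )
    return NetworkTable(rows), truth


# ---------------------------------------------------------------------------
# Compendium


def _solve_fixed_point(truth: GroundTruth, drive: np.ndarray,
                       fixed: dict[int, float]) -> np.ndarray:
    """Solve (I - B) y = drive with some coordinates pinned."""
    n = len(truth.genes)
    A = np.eye(n) - truth.beta.toarray()
    free = np.array([i for i in range(n) if i not in fixed], dtype=int)
    y = np.zeros(n)
    for i, v in fixed.items():
        y[i] = v
    if free.size:
        rhs = drive[free].copy()
        if fixed:
            fixed_idx = np.array(sorted(fixed), dtype=int)
            rhs -= A[np.ix_(free, fixed_idx)] @ y[fixed_idx]
        y[free] = np.linalg.solve(A[np.ix_(free, free)], rhs)
    return np.clip(y, EXPRESSION_FLOOR, EXPRESSION_CEILING)


def _scenario_fixed(truth: GroundTruth, scenario: PerturbationScenario,
                    system: SignalSystem | None) -> dict[int, float]:
    fixed: dict[int, float] = {}
    for g in scenario.knockouts:
        fixed[truth.index(g)] = EXPRESSION_FLOOR
    for g in scenario.overexpressions:
        fixed[truth.index(g)] = EXPRESSION_CEILING
    if scenario.environment:
        if system is None:
            raise ValueError("environmental scenario needs a signal system")
        shifts: dict[str, float] = {}
        for eff, delta in scenario.environment:
            for entry in system.entries_for_effector(eff):
                if entry.is_activity_only:
                    continue  # activity switches alter B, out of scope here
                shifts[entry.tf_id] = (shifts.get(entry.tf_id, 0.0)
                                       + system.omega * entry.kappa * delta)
        for tf, shift in shifts.items():
            i = truth.index(tf)
            fixed[i] = float(np.clip(truth.y_star[i] + shift,
                                     EXPRESSION_FLOOR, EXPRESSION_CEILING))
    return fixed


def simulate_compendium(truth: GroundTruth, n_wt: int,
                        scenarios: Sequence[PerturbationScenario] = (),
                        noise_sd: float = 0.0, seed: int = 0,
                        system: SignalSystem | None = None) -> ExpressionTable:
    """Steady-state arrays: wild-type replicates plus one array per scenario.

    Each array solves the linear fixed point ``(I - B) y = beta0 + eta``
    with Gaussian drive noise; scenario overrides pin knocked-out genes to
    the floor, over-expressed genes to the ceiling and effector-shifted
    TFs to their shifted value.  Values are clamped to [0, 14] log2 units.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if truth.spectral_radius() >= 1.0:
        raise ValueError(
            "ground-truth TF subnetwork is unstable (spectral radius >= 1); "
            "no steady state exists"
        )
    rng = _rng(seed, "compendium")
    n = len(truth.genes)
    array_ids: list[str] = []
    cols: list[np.ndarray] = []
    meta: dict[str, ArrayMeta] = {}

    for w in range(n_wt):
        eta = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        y = _solve_fixed_point(truth, truth.beta0 + eta, {})
        aid = f"wt_{w:03d}"
        array_ids.append(aid)
        cols.append(y)
        meta[aid] = ArrayMeta("wild_type", [], "none", [])

    for s, scn in enumerate(scenarios):
        eta = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        fixed = _scenario_fixed(truth, scn, system)
        y = _solve_fixed_point(truth, truth.beta0 + eta, fixed)
        aid = f"scn_{s:03d}"
        array_ids.append(aid)
        cols.append(y)
        # every gene whose equation was overridden (pinned or rewired) is
        # recorded as perturbed so training can drop it for those genes
        overridden = sorted(scn.genetic_genes()
                            | {truth.genes[i] for i in fixed})
        if scn.knockouts or scn.overexpressions or scn.rewirings:
            kind = ("knockout" if scn.knockouts else
                    "overexpression" if scn.overexpressions else "rewiring")
            meta[aid] = ArrayMeta("genetic", overridden, kind,
                                  list(scn.environment))
        elif scn.environment:
            meta[aid] = ArrayMeta("environmental", overridden, "none",
                                  list(scn.environment))
        else:
            meta[aid] = ArrayMeta("wild_type", [], "none", [])

    values = np.column_stack(cols) if cols else np.zeros((n, 0))
    return ExpressionTable(list(truth.genes), array_ids, values, meta)


def generate_training_scenarios(
    truth: GroundTruth, n_arrays: int, seed: int = 0,
    pin_probability: float = 0.6, max_delta: float = 2.0,
    include_knockouts: bool = False,
) -> tuple[SignalSystem, list[PerturbationScenario]]:
    """Well-conditioned training design: per-array random TF pinnings.

    Builds a unit-kappa expression-type effector for every TF and emits
    ``n_arrays`` environmental scenarios, each pinning a random TF subset
    at random shifts within ``max_delta`` log2 units.  Because unpinned
    genes keep exact linear equations while pinned TFs vary freely, a
    noise-free compendium from these scenarios identifies the true
    coefficients exactly.

    With ``include_knockouts`` one knockout scenario per gene is appended,
    so every gene's capacity floor in the resulting compendium reaches the
    knockout expression level (as in a real compendium containing deletion
    strains); the floor-clamped ripples these arrays introduce are dropped
    per gene during fitting but make the capacity bounds realistic.
    """
    rng = _rng(seed, "scenarios")
    system = SignalSystem([
        SignalEntry(t, f"train_eff_{k:03d}", "I", kappa=1.0)
        for k, t in enumerate(truth.tf_ids)
    ])
    scenarios = []
    for _ in range(n_arrays):
        env = [(f"train_eff_{k:03d}", float(rng.uniform(-max_delta, max_delta)))
               for k in range(len(truth.tf_ids))
               if rng.random() < pin_probability]
        scenarios.append(PerturbationScenario(environment=env))
    if include_knockouts:
        for g in truth.genes:
            scenarios.append(PerturbationScenario(knockouts=[g]))
    return system, scenarios


# ---------------------------------------------------------------------------
# Toy metabolic model


def generate_toy_metabolic_model(
    n_internal: int, redundancy: int = 0, seed: int = 0,
    enzyme_genes: Sequence[str] | None = None,
) -> tuple[MetabolicModelFile, MetabolicGroundTruth]:
    """Uptake -> linear enzyme chain -> biomass, with OR-isozyme steps.

    The first ``redundancy`` chain steps carry two OR-combined isozyme
    genes (individually dispensable); every other step has a single
    essential enzyme gene.  Analytic optimal growth equals the uptake
    capacity (10), recorded in the ground truth.  ``enzyme_genes``
    optionally supplies gene ids (e.g. from a generated TRN) so GPRs
    reference regulatory-model genes.
    """
    if n_internal < 3:
        raise ValueError("n_internal must be >= 3")
    if not 0 <= redundancy <= n_internal:
        raise ValueError("redundancy must be in [0, n_internal]")
    rng = _rng(seed, "metabolic")
    n_needed = n_internal + redundancy
    if enzyme_genes is not None:
        if len(enzyme_genes) < n_needed:
            raise ValueError(
                f"need {n_needed} enzyme genes, got {len(enzyme_genes)}"
            )
        pool = list(rng.choice(list(enzyme_genes), size=n_needed,
                               replace=False))
    else:
        pool = [f"mg{i:03d}" for i in range(n_needed)]

    metabolites = [f"M{i}" for i in range(n_internal + 1)]
    uptake_cap = 10.0
    reactions = [Reaction("EX_upt", {"M0": 1.0}, 0.0, uptake_cap,
                          gpr=None, is_exchange=True)]
    step_genes: dict[str, list[str]] = {}
    essential: set[str] = set()
    isozymes: set[str] = set()
    gi = 0
    for i in range(1, n_internal + 1):
        rid = f"R{i}"
        stoich = {f"M{i-1}": -1.0, f"M{i}": 1.0}
        if i <= redundancy:
            g1, g2 = pool[gi], pool[gi + 1]
            gi += 2
            gpr = parse_gpr(f"{g1} or {g2}")
            step_genes[rid] = [g1, g2]
            isozymes |= {g1, g2}
        else:
            g = pool[gi]
            gi += 1
            gpr = parse_gpr(g)
            step_genes[rid] = [g]
            essential.add(g)
        reactions.append(Reaction(rid, stoich, 0.0, 1000.0, gpr=gpr))
    reactions.append(Reaction("BIO", {f"M{n_internal}": -1.0}, 0.0, 1000.0))

    model = MetabolicModelFile(metabolites, reactions, "BIO")
    truth = MetabolicGroundTruth(
        optimal_growth=uptake_cap,
        essential_genes=essential,
        isozyme_genes=isozymes,
        step_genes=step_genes,
        uptake_reaction="EX_upt",
    )
    return model, truth


# ---------------------------------------------------------------------------
# Signal transduction entries


def generate_sts(truth: GroundTruth, n_systems: int,
                 seed: int = 0, omega: float = 1.0) -> SignalSystem:
    """Random effector entries on distinct TFs.

    Roughly 20% of entries are activity-only (the effector disables the
    TF); the rest shift expression with log-uniform |kappa| in [0.1, 2]
    and a fair-coin sign.
    """
    if n_systems > len(truth.tf_ids):
        raise ValueError("n_systems exceeds the number of TFs")
    rng = _rng(seed, "sts")
    tfs = list(rng.choice(truth.tf_ids, size=n_systems, replace=False))
    entries = []
    for i, tf in enumerate(tfs):
        eff = f"eff{i:03d}"
        if rng.random() < 0.2:
            entries.append(SignalEntry(
                tf, eff, "activity_only", functional_with_effector=False,
            ))
        else:
            kappa = float(np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
            if rng.random() < 0.5:
                kappa = -kappa
            typ = str(rng.choice(["I", "II", "III", "IV"]))
            entries.append(SignalEntry(tf, eff, typ, kappa=kappa))
    return SignalSystem(entries, omega=omega)


# ---------------------------------------------------------------------------
# Annotation


def generate_annotation(truth: GroundTruth, n_terms: int,
                        max_level: int = 7, seed: int = 0) -> GoAnnotation:
    """Random term -> gene annotation over the TRN gene universe."""
    rng = _rng(seed, "annotation")
    terms: dict[str, tuple[int, set[str]]] = {}
    for t in range(n_terms):
        level = int(rng.integers(1, max_level + 1))
        size = int(rng.integers(2, max(3, len(truth.genes) // 4)))
        genes = set(rng.choice(truth.genes, size=min(size, len(truth.genes)),
                               replace=False))
        terms[f"T{t:04d}"] = (level, genes)
    return GoAnnotation(terms, set(truth.genes))


# ---------------------------------------------------------------------------
# Scenario suite with analytic growth truth


def generate_scenarios(truth: GroundTruth, system: SignalSystem | None,
                       n: int, seed: int = 0,
                       focus_genes: Sequence[str] | None = None,
                       p_focus: float = 0.5,
                       uptake: tuple[str, float] | None = None,
                       ) -> list[PerturbationScenario]:
    """Random single-perturbation scenarios for growth benchmarking.

    Mixes knockouts, over-expressions, effector shifts and — when
    ``uptake = (reaction_id, max_ub)`` is given — nutrient-limitation
    scenarios capping that exchange bound at a random fraction.
    ``focus_genes`` (e.g. the metabolic enzyme genes) are over-sampled with
    probability ``p_focus`` so the suite contains scenarios with strong
    growth phenotypes, not just regulatory ripples.
    """
    rng = _rng(seed, "scenarios")
    expr_effectors = ([e.effector_id for e in system.entries
                       if not e.is_activity_only] if system else [])
    focus = [g for g in (focus_genes or []) if g in set(truth.genes)]

    def _pick_gene() -> str:
        if focus and rng.random() < p_focus:
            return str(rng.choice(focus))
        return str(rng.choice(truth.genes))

    out: list[PerturbationScenario] = []
    for _ in range(n):
        kind = rng.random()
        if uptake is not None and kind < 0.4:
            rxn, max_ub = uptake
            frac = float(rng.uniform(0.0, 1.0))
            out.append(PerturbationScenario(
                exchange_overrides=[(rxn, 0.0, frac * max_ub)]))
        elif kind < 0.7 or not expr_effectors:
            out.append(PerturbationScenario(knockouts=[_pick_gene()]))
        elif kind < 0.9:
            out.append(PerturbationScenario(overexpressions=[_pick_gene()]))
        else:
            eff = str(rng.choice(expr_effectors))
            delta = float(rng.uniform(-3.0, 3.0))
            out.append(PerturbationScenario(environment=[(eff, delta)]))
    return out


def ground_truth_growth(
    truth: GroundTruth,
    met_model: MetabolicModelFile,
    system: SignalSystem | None,
    scenario: PerturbationScenario,
    params: TrameParams | None = None,
    gamma: float = 1.0,
) -> float:
    """Analytic relative growth implied by the generator's own parameters.

    Uses the exact linear fixed point under the scenario (no regression,
    no QP), ungated fold-change ratios with knocked-out genes at zero
    activity, then the same bound-scaling and LP as the pipeline.  Serves
    as the recoverable truth for growth-prediction benchmarks.
    """
    if params is None:
        params = TrameParams()
    fixed = _scenario_fixed(truth, scenario, system)
    y_true = _solve_fixed_point(truth, truth.beta0, fixed)

    span = EXPRESSION_CEILING - EXPRESSION_FLOOR
    cost = gamma * float(np.mean(np.abs(y_true - truth.y_star))) / span

    ratios = {g: float(2.0 ** (y_true[i] - truth.y_star[i]))
              for i, g in enumerate(truth.genes)}
    for g in scenario.knockouts:
        ratios[g] = 0.0

    ref = fba(met_model)
    if ref.status != "optimal" or not ref.growth:
        raise RuntimeError("toy metabolic model has no wild-type growth")
    envelope = fva(met_model)
    gated: dict[str, tuple[float, float]] = {}
    for r in met_model.reactions:
        lo, hi = envelope[r.id]
        if r.gpr is not None:
            p = min(max(0.0, r.gpr.evaluate(ratios, default=1.0)),
                    params.p_cap)
            if hi > 0:
                hi *= p
            if lo < 0:
                lo *= p
        gated[r.id] = (lo, hi)
    bounds = FluxBounds(gated)
    try:
        bounds = bounds.with_overrides(scenario.exchange_overrides)
    except ValueError:
        return 0.0
    state = fba(met_model, bounds)
    benefit = (max(0.0, state.growth / ref.growth)
               if state.status == "optimal" and state.growth is not None
               else 0.0)
    return max(0.0, benefit - cost)
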