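"""Linear transcriptional model: fitting, steady-state prediction, neighborhoods.

Each gene's log2 expression is modeled as an affine function of the log2
expression of its transcription-factor regulators:

    y_i = beta0_i + sum_j beta_ij * y_j        (j over regulators of i)

Coefficients are fitted per gene by (optionally sign-constrained) ridge
least squares across the compendium arrays.  Only the steady state is
modeled; the coefficients feed the expression-balance QP downstream.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import lsq_linear

from .io import ExpressionTable, NetworkTable

logger = logging.getLogger(__name__)


class FitError(ValueError):
    pass


@dataclass
class RegulatoryModel:
    """Trained linear transcriptional model.

    Attributes
    ----------
    genes : ordered gene ids (defines the row/column order of all arrays).
    tf_set : genes acting as regulators somewhere in the network.
    beta0 : per-gene basal coefficient, log2 units.
    beta : sparse (n_genes x n_genes) coefficient matrix; ``beta[i, j]`` is
        the effect of TF ``genes[j]`` on gene ``genes[i]``; the sparsity
        pattern is a subset of the network edges.
    y_min, y_max : per-gene capacity bounds (compendium min/max, log2).
    y_wt, sigma_wt : per-gene wild-type mean and standard deviation.
    """

    genes: list[str]
    tf_set: set[str]
    beta0: np.ndarray
    beta: sparse.csr_matrix
    y_min: np.ndarray
    y_max: np.ndarray
    y_wt: np.ndarray
    sigma_wt: np.ndarray
    edge_signs: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.genes)
        for name in ("beta0", "y_min", "y_max", "y_wt", "sigma_wt"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        self.beta = sparse.csr_matrix(self.beta)
        if self.beta.shape != (n, n):
            raise ValueError(f"beta must be {n}x{n}")
        if np.any(self.sigma_wt < 0):
            raise ValueError("sigma_wt must be non-negative")
        if np.any(self.y_min > self.y_max):
            raise ValueError("y_min must be <= y_max elementwise")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def tf_list(self) -> list[str]:
        """TFs in gene order (stable across calls)."""
        return [g for g in self.genes if g in self.tf_set]

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in model") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._index

    def clamp(self, y: np.ndarray) -> np.ndarray:
        return np.clip(y, self.y_min, self.y_max)

    def copy(self) -> "RegulatoryModel":
        return RegulatoryModel(
            genes=list(self.genes),
            tf_set=set(self.tf_set),
            beta0=self.beta0.copy(),
            beta=self.beta.copy(),
            y_min=self.y_min.copy(),
            y_max=self.y_max.copy(),
            y_wt=self.y_wt.copy(),
            sigma_wt=self.sigma_wt.copy(),
            edge_signs=dict(self.edge_signs),
        )

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        coo = self.beta.tocoo()
        return {
            "genes": self.genes,
            "tf_set": sorted(self.tf_set),
            "beta0": self.beta0.tolist(),
            "beta_triplets": [
                [self.genes[i], self.genes[j], float(v)]
                for i, j, v in zip(coo.row.tolist(), coo.col.tolist(),
                                   coo.data.tolist())
            ],
            "y_min": self.y_min.tolist(),
            "y_max": self.y_max.tolist(),
            "y_wt": self.y_wt.tolist(),
            "sigma_wt": self.sigma_wt.tolist(),
            "edge_signs": [[r, t, s] for (r, t), s in
                           sorted(self.edge_signs.items())],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RegulatoryModel":
        genes = list(doc["genes"])
        index = {g: i for i, g in enumerate(genes)}
        n = len(genes)
        beta = sparse.lil_matrix((n, n))
        for tgt, reg, v in doc["beta_triplets"]:
            beta[index[tgt], index[reg]] = v
        return cls(
            genes=genes,
            tf_set=set(doc["tf_set"]),
            beta0=np.asarray(doc["beta0"], dtype=float),
            beta=beta.tocsr(),
            y_min=np.asarray(doc["y_min"], dtype=float),
            y_max=np.asarray(doc["y_max"], dtype=float),
            y_wt=np.asarray(doc["y_wt"], dtype=float),
            sigma_wt=np.asarray(doc["sigma_wt"], dtype=float),
            edge_signs={(r, t): s for r, t, s in doc.get("edge_signs", [])},
        )


# ---------------------------------------------------------------------------
# Fitting


def _fit_single_gene(y: np.ndarray, X: np.ndarray, signs: Sequence[str],
                     ridge: float, sign_constrained: bool) -> np.ndarray:
    """Solve min ||y - b0 - X b||^2 + ridge * ||b||^2 for one gene.

    Returns the coefficient vector ``[b0, b_1..b_k]``.  When
    ``sign_constrained``, each b_j is restricted to >= 0 for "+" edges and
    <= 0 for "-" edges ("+/-" stays free); the intercept is always free.
    The ridge never penalizes the intercept.
    """
    n, k = X.shape
    A = np.hstack([np.ones((n, 1)), X])
    if ridge > 0 and k > 0:
        pen = np.hstack([np.zeros((k, 1)), np.sqrt(ridge) * np.eye(k)])
        A = np.vstack([A, pen])
        y = np.concatenate([y, np.zeros(k)])
    if not sign_constrained or k == 0:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return coef
    lb = np.full(k + 1, -np.inf)
    ub = np.full(k + 1, np.inf)
    for j, s in enumerate(signs, start=1):
        if s == "+":
            lb[j] = 0.0
        elif s == "-":
            ub[j] = 0.0
    res = lsq_linear(A, y, bounds=(lb, ub), tol=1e-12)
    return res.x


def fit(network: NetworkTable, compendium: ExpressionTable,
        ridge: float = 0.0, sign_constrained: bool = False) -> RegulatoryModel:
    """Fit the per-gene linear model from a compendium.

    All compendium genes enter the model; the network supplies the
    regulator sets and edge signs.  Capacity bounds are per-gene min/max
    over all arrays; wild-type statistics are mean/sd over the wild-type
    arrays.  Arrays where a gene is itself directly perturbed (knocked
    out, over-expressed, rewired, or pinned by an effector) are excluded
    from that gene's regression — its equation is overridden there — but
    still contribute to every other gene's fit and to the capacity bounds.
    """
    if ridge < 0:
        raise FitError("ridge must be non-negative")
    missing = network.genes() - set(compendium.gene_ids)
    if missing:
        raise FitError(
            f"network genes absent from compendium: {sorted(missing)[:5]}"
        )
    wt_arrays = compendium.arrays_of_class("wild_type")
    if len(wt_arrays) < 2:
        raise FitError("need >= 2 wild-type arrays for WT statistics")

    genes = list(compendium.gene_ids)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    values = compendium.values

    tf_set = network.regulators()
    regulators: dict[str, list[tuple[str, str]]] = {g: [] for g in genes}
    edge_signs: dict[tuple[str, str], str] = {}
    for e in network.edges:
        regulators[e.target].append((e.regulator, e.sign))
        edge_signs[(e.regulator, e.target)] = e.sign

    # arrays where a gene's own equation is overridden (genetic edit or a
    # direct environmental constraint) are masked for that gene's fit
    perturbed_in: dict[str, set[int]] = {}
    for a_idx, aid in enumerate(compendium.array_ids):
        meta = compendium.array_meta[aid]
        for g in meta.perturbed_genes:
            perturbed_in.setdefault(g, set()).add(a_idx)

    wt_cols = [compendium.array_ids.index(a) for a in wt_arrays]
    wt_block = values[:, wt_cols]

    beta0 = np.zeros(n)
    beta = sparse.lil_matrix((n, n))
    for g in genes:
        i = index[g]
        regs = sorted(regulators[g])
        mask = np.ones(values.shape[1], dtype=bool)
        for a_idx in perturbed_in.get(g, ()):
            mask[a_idx] = False
        y = values[i, mask]
        X = np.column_stack(
            [values[index[r], mask] for r, _ in regs]
        ) if regs else np.empty((y.size, 0))
        k = len(regs)
        gene_ridge = ridge
        if y.size < k + 1:
            warnings.warn(
                f"gene {g!r}: {y.size} training arrays for {k} regulators; "
                "enforcing ridge floor 1e-3", stacklevel=2,
            )
            gene_ridge = max(gene_ridge, 1e-3)
        coef = _fit_single_gene(y, X, [s for _, s in regs],
                                gene_ridge, sign_constrained)
        beta0[i] = coef[0]
        for (r, _), b in zip(regs, coef[1:]):
            beta[i, index[r]] = b

    return RegulatoryModel(
        genes=genes,
        tf_set=set(tf_set),
        beta0=beta0,
        beta=beta.tocsr(),
        y_min=values.min(axis=1),
        y_max=values.max(axis=1),
        y_wt=wt_block.mean(axis=1),
        sigma_wt=wt_block.std(axis=1, ddof=1),
        edge_signs=edge_signs,
    )


# ---------------------------------------------------------------------------
# Prediction and network neighborhoods


def predict_steady_state(model: RegulatoryModel,
                         tf_profile: Mapping[str, float]) -> np.ndarray:
    """Propagate a TF expression profile through the linear model.

    Returns per-gene expression aligned with ``model.genes``:
    ``clamp(beta0 + beta @ y_tf)`` where the beta columns of non-TF genes
    are structurally zero.
    """
    missing = [t for t in model.tf_list if t not in tf_profile]
    if missing:
        raise KeyError(f"tf_profile missing TFs: {missing[:5]}")
    y_tf = np.zeros(model.n_genes)
    for t in model.tf_list:
        y_tf[model.index(t)] = tf_profile[t]
    y_hat = model.beta0 + model.beta @ y_tf
    return model.clamp(y_hat)


def neighborhood(network: NetworkTable, seeds: Iterable[str],
                 radius: int, undirected: bool = False) -> set[str]:
    """Genes reachable from any seed within ``radius`` regulatory hops.

    Follows edge direction (regulator -> target) by default; seeds are
    always included.  A seed absent from the network is kept in the output
    with a warning.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    adj: dict[str, set[str]] = {}
    net_genes = network.genes()
    for e in network.edges:
        adj.setdefault(e.regulator, set()).add(e.target)
        if undirected:
            adj.setdefault(e.target, set()).add(e.regulator)
    seeds = list(seeds)
    for s in seeds:
        if s not in net_genes:
            warnings.warn(f"seed {s!r} not in network; kept in output",
                          stacklevel=2)
    out = set(seeds)
    frontier = deque((s, 0) for s in seeds)
    dist = {s: 0 for s in seeds}
    while frontier:
        node, d = frontier.popleft()
        if d == radius:
            continue
        for nxt in adj.get(node, ()):
            if nxt not in dist or dist[nxt] > d + 1:
                dist[nxt] = d + 1
                out.add(nxt)
                frontier.append((nxt, d + 1))
    return out
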