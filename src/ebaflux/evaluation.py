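"""Assessment protocol: correlation scoring against an empirical null.

A predicted profile is scored by Pearson correlation with the measured
profile, globally (all genes) and locally (genes within two regulatory
links of the perturbed genes).  Significance is empirical: the observed
correlation is ranked against correlations of randomly drawn compendium
columns with the same measured profile, with add-one smoothing so p is
never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionTable, NetworkTable
from .transcriptional import neighborhood

WELL_PREDICTED_ALPHA = 0.05


class EvaluationError(ValueError):
    pass


def pcc(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Pearson product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("pcc requires two equal-length vectors")
    if x.size < 3:
        raise EvaluationError("pcc requires length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EvaluationError("pcc undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ArrayRecord:
    array_id: str
    pcc_global: float
    pcc_local: float | None            # None when the local set is degenerate
    local_undefined: bool
    local_genes: list[str]
    null_pccs: np.ndarray
    p_value: float
    p_value_local: float | None
    well_predicted: bool


@dataclass
class EvaluationReport:
    records: list[ArrayRecord]
    threshold: float                   # TH = mean global PCC over records
    fraction_above_threshold: float    # strict inequality
    fraction_well_predicted: float


def _empirical_p(observed: float, null: np.ndarray) -> float:
    # add-one smoothing: p is never exactly 0
    return float((1 + int((null >= observed).sum())) / (1 + null.size))


def _pcc_columns(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of M with y (vectorized)."""
    Mc = M - M.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Mc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc.T @ yc) / denom
    return r


def evaluate_array(
    pred: np.ndarray,
    measured: np.ndarray,
    compendium: ExpressionTable,
    network: NetworkTable,
    perturbed_genes: Iterable[str],
    n_null: int = 100,
    seed: int | None = None,
    array_id: str = "",
    exclude_array: str | None = None,
    radius: int = 2,
) -> ArrayRecord:
    """Score one predicted array against its measurement.

    ``pred`` and ``measured`` are aligned with ``compendium.gene_ids``.
    The null distribution draws ``n_null`` compendium columns uniformly
    with replacement (excluding ``exclude_array``, normally the evaluated
    array itself) and correlates each with the measured profile; the
    one-sided p-value is the smoothed fraction of null correlations at or
    above the observed one.
    """
    if n_null < 100:
        raise EvaluationError("n_null must be >= 100")
    pred = np.asarray(pred, dtype=float)
    measured = np.asarray(measured, dtype=float)
    n_genes = compendium.n_genes
    if pred.shape != (n_genes,) or measured.shape != (n_genes,):
        raise EvaluationError("profiles must align with compendium genes")

    pcc_global = pcc(pred, measured)

    local = sorted(
        neighborhood(network, list(perturbed_genes), radius)
        & set(compendium.gene_ids)
    )
    idx = {g: i for i, g in enumerate(compendium.gene_ids)}
    pcc_local: float | None = None
    local_undefined = True
    if len(local) >= 3:
        li = [idx[g] for g in local]
        try:
            pcc_local = pcc(pred[li], measured[li])
            local_undefined = False
        except EvaluationError:
            pcc_local = None

    rng = np.random.default_rng(seed)
    pool = [a for a in compendium.array_ids if a != exclude_array]
    if not pool:
        raise EvaluationError("no compendium arrays available for the null")
    pool_idx = [compendium.array_ids.index(a) for a in pool]
    draws = rng.integers(0, len(pool), size=n_null)
    cols = compendium.values[:, [pool_idx[d] for d in draws]]
    null_global = _pcc_columns(cols, measured)
    null_local = None
    if pcc_local is not None:
        li = [idx[g] for g in local]
        null_local = _pcc_columns(cols[li, :], measured[li])

    p_global = _empirical_p(pcc_global, null_global)
    p_local = (_empirical_p(pcc_local, null_local)
               if null_local is not None else None)

    return ArrayRecord(
        array_id=array_id,
        pcc_global=pcc_global,
        pcc_local=pcc_local,
        local_undefined=local_undefined,
        local_genes=local,
        null_pccs=null_global,
        p_value=p_global,
        p_value_local=p_local,
        well_predicted=p_global < WELL_PREDICTED_ALPHA,
    )


def summarize(records: Sequence[ArrayRecord]) -> EvaluationReport:
    """Aggregate per-array records: mean-PCC threshold and fractions.

    The threshold TH is the mean global PCC over all records; the fraction
    above TH uses strict inequality (ties count below), so identical
    records give fraction 0.
    """
    if not records:
        raise EvaluationError("summarize requires at least one record")
    pccs = np.array([r.pcc_global for r in records])
    th = float(pccs.mean())
    return EvaluationReport(
        records=list(records),
        threshold=th,
        fraction_above_threshold=float((pccs > th).mean()),
        fraction_well_predicted=float(
            np.mean([r.well_predicted for r in records])
        ),
    )
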