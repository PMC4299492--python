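"""Greedy knockout selection maximizing annotation-term coverage.

Candidate knockouts are ranked by marginal gain in covered eligible terms
(a term is covered once at least ``k`` of its genes have been perturbed),
a classic monotone-submodular objective for which the greedy algorithm
carries the (1 - 1/e) approximation guarantee.  Ties break toward the
candidate whose regulatory neighborhood shows more expression variability
in the compendium, then lexicographically so reruns are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import ExpressionTable, GoAnnotation, NetworkTable
from .transcriptional import neighborhood

DEFAULT_MAX_LEVEL = 5
DEFAULT_SIZE_MIN = 3
DEFAULT_SIZE_MAX = 500


@dataclass
class DesignResult:
    ranked: list[str]
    cumulative_new_terms: list[int]
    variability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.ranked)) != len(self.ranked):
            raise ValueError("ranked list contains duplicates")
        for a, b in zip(self.cumulative_new_terms, self.cumulative_new_terms[1:]):
            if b < a:
                raise ValueError("cumulative coverage must be non-decreasing")


def eligible_terms(annotation: GoAnnotation,
                   max_level: int = DEFAULT_MAX_LEVEL,
                   size_min: int = DEFAULT_SIZE_MIN,
                   size_max: int = DEFAULT_SIZE_MAX) -> set[str]:
    """Terms passing the hierarchy-level and annotation-size filters."""
    if size_min < 1:
        raise ValueError("size_min must be >= 1")
    return {
        term for term, (level, genes) in annotation.terms.items()
        if level <= max_level and size_min <= len(genes) <= size_max
    }


def coverage(terms: dict[str, set[str]], perturbed: Iterable[str],
             k: int = 1) -> set[str]:
    """Terms with at least ``k`` annotated genes in the perturbed set."""
    if k < 1:
        raise ValueError("k must be >= 1")
    perturbed = set(perturbed)
    return {t for t, genes in terms.items() if len(genes & perturbed) >= k}


def variability_score(gene: str, network: NetworkTable,
                      compendium: ExpressionTable, radius: int = 2) -> float:
    """Mean compendium expression variance over the gene's downstream
    radius-``radius`` neighborhood (the gene's own variance if isolated)."""
    if gene not in network.genes():
        raise KeyError(f"gene {gene!r} not in network")
    hood = neighborhood(network, [gene], radius) & set(compendium.gene_ids)
    if not hood:
        hood = {gene} & set(compendium.gene_ids)
    if not hood:
        raise KeyError(f"gene {gene!r} not in compendium")
    variances = [float(np.var(compendium.gene_row(g))) for g in sorted(hood)]
    return float(np.mean(variances))


def greedy_design(
    annotation: GoAnnotation,
    network: NetworkTable,
    compendium: ExpressionTable,
    current_perturbed: Iterable[str],
    candidates: Sequence[str],
    budget: int,
    k: int = 1,
    max_level: int = DEFAULT_MAX_LEVEL,
    size_min: int = DEFAULT_SIZE_MIN,
    size_max: int = DEFAULT_SIZE_MAX,
) -> DesignResult:
    """Rank candidate knockouts by marginal newly-covered-term count.

    Each round picks the candidate adding the most newly covered eligible
    terms; ties break by higher variability score, then by id.  Once no
    candidate covers anything new, the remaining budget is filled in
    variability order.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    current = set(current_perturbed)
    overlap = current & set(candidates)
    if overlap:
        raise ValueError(
            f"candidates already perturbed: {sorted(overlap)[:5]}"
        )
    eligible = eligible_terms(annotation, max_level, size_min, size_max)
    terms = {t: annotation.terms[t][1] for t in eligible}

    var_score = {
        c: (variability_score(c, network, compendium)
            if c in network.genes() and c in set(compendium.gene_ids)
            else 0.0)
        for c in candidates
    }

    ranked: list[str] = []
    cumulative: list[int] = []
    chosen = set(current)
    covered = coverage(terms, chosen, k)
    remaining = sorted(candidates)
    exhausted = False
    while remaining and len(ranked) < budget:
        if not exhausted:
            best, best_key = None, None
            for c in remaining:
                gain = len(coverage(terms, chosen | {c}, k) - covered)
                key = (gain, var_score[c], _neg_lex(c))
                if best_key is None or key > best_key:
                    best, best_key = c, key
            if best_key[0] == 0:
                exhausted = True
                continue
            pick = best
        else:
            pick = max(remaining, key=lambda c: (var_score[c], _neg_lex(c)))
        ranked.append(pick)
        remaining.remove(pick)
        chosen.add(pick)
        covered = coverage(terms, chosen, k)
        cumulative.append(len(covered) - len(coverage(terms, current, k)))

    return DesignResult(ranked=ranked, cumulative_new_terms=cumulative,
                        variability=var_score)


class _neg_lex(str):
    """Wrapper inverting lexicographic order so max() prefers smaller ids."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
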