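"""Readers/writers for the on-disk artifact dialects.

All formats are plain text so fixtures diff cleanly:

* regulatory network — 4-column TSV ``regulator  target  sign  evidence``
  with ``sign`` in ``{+, -, +/-}`` and ``evidence`` in
  ``{confirmed, strong, weak, inferred}``;
* expression compendium — TSV matrix (first column gene ids, header row
  array ids, log2 values) plus a per-array metadata TSV;
* metabolic model — a small JSON dialect (documented in
  :func:`read_metabolic_model`) with a minimal SBML-L3/fbc reader as a
  secondary entry point;
* GO annotation — 3-column TSV ``term_id  level  gene_id``.

Gene and array ids are opaque, case-sensitive strings; expression values
are log2-scale by contract and are never renormalized here.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._gpr import GPRNode, GPRSyntaxError, parse_gpr

logger = logging.getLogger(__name__)

EVIDENCE_TIERS = ("confirmed", "strong", "weak", "inferred")
_TIER_RANK = {t: i for i, t in enumerate(EVIDENCE_TIERS)}
SIGNS = ("+", "-", "+/-")
ARRAY_CLASSES = ("wild_type", "genetic", "environmental")
PERTURBATION_KINDS = ("knockout", "overexpression", "rewiring", "none")


class FormatError(ValueError):
    """Raised for malformed input artifacts (bad token, bad shape, ...)."""


# ---------------------------------------------------------------------------
# Regulatory network


@dataclass(frozen=True)
class NetworkEdge:
    regulator: str
    target: str
    sign: str            # "+", "-" or "+/-"
    evidence: str        # confirmed | strong | weak | inferred


@dataclass
class NetworkTable:
    """Signed, evidence-tiered TF -> target edge list.

    Duplicate (regulator, target) pairs are merged on construction; a sign
    conflict collapses to the dual sign ``+/-`` and the merged edge keeps
    the strongest evidence tier.
    """

    edges: list[NetworkEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: dict[tuple[str, str], NetworkEdge] = {}
        for e in self.edges:
            if not e.regulator or not e.target:
                raise FormatError("regulator/target ids must be non-empty")
            if e.sign not in SIGNS:
                raise FormatError(f"invalid sign token {e.sign!r}")
            if e.evidence not in EVIDENCE_TIERS:
                raise FormatError(f"invalid evidence tier {e.evidence!r}")
            key = (e.regulator, e.target)
            old = merged.get(key)
            if old is None:
                merged[key] = e
            else:
                sign = old.sign if old.sign == e.sign else "+/-"
                ev = min(old.evidence, e.evidence, key=_TIER_RANK.__getitem__)
                merged[key] = NetworkEdge(e.regulator, e.target, sign, ev)
        self.edges = list(merged.values())

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.regulator)
            out.add(e.target)
        return out

    def regulators(self) -> set[str]:
        return {e.regulator for e in self.edges}

    def regulators_of(self, gene: str) -> list[NetworkEdge]:
        return [e for e in self.edges if e.target == gene]

    def targets_of(self, gene: str) -> list[NetworkEdge]:
        return [e for e in self.edges if e.regulator == gene]

    def filter_evidence(self, min_evidence: str) -> "NetworkTable":
        if min_evidence not in EVIDENCE_TIERS:
            raise FormatError(f"unknown evidence tier {min_evidence!r}")
        cut = _TIER_RANK[min_evidence]
        return NetworkTable(
            [e for e in self.edges if _TIER_RANK[e.evidence] <= cut]
        )


def read_network(path: str | Path, min_evidence: str = "inferred") -> NetworkTable:
    """Read a 4-column network TSV, keeping rows at/above ``min_evidence``.

    The header row is optional and detected by its sign column not being a
    valid sign token.  Malformed sign or evidence tokens raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    edges: list[NetworkEdge] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(parts)}"
                )
            reg, tgt, sign, ev = (p.strip() for p in parts)
            if lineno == 1 and sign not in SIGNS and ev not in EVIDENCE_TIERS:
                continue  # header row
            if sign not in SIGNS:
                raise FormatError(
                    f"{path}:{lineno}: invalid sign token {sign!r} "
                    f"(expected one of {', '.join(SIGNS)})"
                )
            if ev not in EVIDENCE_TIERS:
                raise FormatError(
                    f"{path}:{lineno}: invalid evidence tier {ev!r}"
                )
            edges.append(NetworkEdge(reg, tgt, sign, ev))
    table = NetworkTable(edges).filter_evidence(min_evidence)
    if len(table) == 0:
        warnings.warn(
            f"no network edges at or above evidence tier {min_evidence!r} "
            f"in {path}", stacklevel=2,
        )
    return table


def write_network(table: NetworkTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("regulator\ttarget\tsign\tevidence\n")
        for e in sorted(table.edges, key=lambda e: (e.regulator, e.target)):
            fh.write(f"{e.regulator}\t{e.target}\t{e.sign}\t{e.evidence}\n")


# ---------------------------------------------------------------------------
# Expression compendium


@dataclass
class ArrayMeta:
    """Per-array annotation: perturbation class and details."""

    array_class: str = "wild_type"
    perturbed_genes: list[str] = field(default_factory=list)
    perturbation_kind: str = "none"
    effectors: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.array_class not in ARRAY_CLASSES:
            raise FormatError(f"invalid array class {self.array_class!r}")
        if self.perturbation_kind not in PERTURBATION_KINDS:
            raise FormatError(
                f"invalid perturbation kind {self.perturbation_kind!r}"
            )


@dataclass
class ExpressionTable:
    """Genes x arrays log2 expression matrix with per-array metadata."""

    gene_ids: list[str]
    array_ids: list[str]
    values: np.ndarray
    array_meta: dict[str, ArrayMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.array_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.array_ids)} arrays"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in expression table")
        gene_set = set(self.gene_ids)
        for aid in self.array_ids:
            meta = self.array_meta.setdefault(aid, ArrayMeta())
            for g in meta.perturbed_genes:
                if g not in gene_set:
                    raise FormatError(
                        f"perturbed gene {g!r} of array {aid!r} absent "
                        "from expression matrix"
                    )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene], :]

    def array_column(self, array_id: str) -> np.ndarray:
        return self.values[:, self.array_ids.index(array_id)]

    def arrays_of_class(self, array_class: str) -> list[str]:
        return [a for a in self.array_ids
                if self.array_meta[a].array_class == array_class]


def _parse_effectors(cell: str) -> list[tuple[str, float]]:
    cell = cell.strip()
    if not cell or cell == "-":
        return []
    out = []
    for item in cell.split(","):
        name, _, val = item.partition(":")
        if not val:
            raise FormatError(f"malformed effector entry {item!r} "
                              "(expected 'id:delta')")
        out.append((name.strip(), float(val)))
    return out


def _format_effectors(effectors: Sequence[tuple[str, float]]) -> str:
    if not effectors:
        return "-"
    return ",".join(f"{e}:{d:g}" for e, d in effectors)


def read_expression(path: str | Path,
                    meta_path: str | Path | None = None) -> ExpressionTable:
    """Read an expression matrix TSV plus optional per-array metadata TSV.

    Matrix: header row of array ids, first column gene ids, tab-separated
    numeric cells.  Meta: columns ``array_id``, ``class``,
    ``perturbation_kind``, ``perturbed_genes`` (comma list or ``-``),
    ``effectors`` (``id:delta`` comma list or ``-``).  Arrays missing from
    the metadata default to wild type with a logged warning.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        array_ids = [h for h in header[1:] if h != ""]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != len(array_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(array_ids) + 1} columns, "
                    f"got {len(parts)}"
                )
            gene = parts[0]
            if gene in gene_ids:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            vals = []
            for j, cell in enumerate(parts[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at gene "
                        f"{gene!r}, array {array_ids[j]!r}"
                    ) from None
                if not np.isfinite(v):
                    raise FormatError(
                        f"{path}: non-finite cell at gene {gene!r}, "
                        f"array {array_ids[j]!r}"
                    )
                vals.append(v)
            gene_ids.append(gene)
            rows.append(vals)
    meta: dict[str, ArrayMeta] = {}
    if meta_path is not None:
        meta = read_array_meta(meta_path)
    for aid in array_ids:
        if aid not in meta:
            logger.warning(
                "array %r missing from metadata; defaulting to wild_type", aid
            )
            meta[aid] = ArrayMeta()
    meta = {a: meta[a] for a in array_ids}
    return ExpressionTable(gene_ids, array_ids, np.array(rows), meta)


def read_array_meta(path: str | Path) -> dict[str, ArrayMeta]:
    path = Path(path)
    meta: dict[str, ArrayMeta] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["array_id", "class", "perturbation_kind",
                    "perturbed_genes", "effectors"]
        if [h.strip() for h in header] != expected:
            raise FormatError(
                f"{path}: metadata header must be {expected}, got {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            aid, cls, kind, genes_cell, eff_cell = (p.strip() for p in parts)
            genes = ([] if genes_cell in ("", "-")
                     else [g.strip() for g in genes_cell.split(",")])
            meta[aid] = ArrayMeta(cls, genes, kind, _parse_effectors(eff_cell))
    return meta


def write_expression(table: ExpressionTable, path: str | Path,
                     meta_path: str | Path | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(table.array_ids) + "\n")
        for i, g in enumerate(table.gene_ids):
            row = "\t".join(repr(float(v)) for v in table.values[i, :])
            fh.write(f"{g}\t{row}\n")
    if meta_path is not None:
        with Path(meta_path).open("w") as fh:
            fh.write("array_id\tclass\tperturbation_kind\t"
                     "perturbed_genes\teffectors\n")
            for aid in table.array_ids:
                m = table.array_meta[aid]
                genes = ",".join(m.perturbed_genes) if m.perturbed_genes else "-"
                fh.write(f"{aid}\t{m.array_class}\t{m.perturbation_kind}\t"
                         f"{genes}\t{_format_effectors(m.effectors)}\n")


# ---------------------------------------------------------------------------
# Metabolic model


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GPRNode | None = None
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise FormatError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )

    def gpr_string(self) -> str:
        return "" if self.gpr is None else self.gpr.to_string()


@dataclass
class MetabolicModelFile:
    """Stoichiometric model: metabolites, bounded reactions with GPRs."""

    metabolites: list[str]
    reactions: list[Reaction]
    biomass_reaction_id: str

    def __post_init__(self) -> None:
        met_set = set(self.metabolites)
        if len(met_set) != len(self.metabolites):
            raise FormatError("duplicate metabolite ids")
        seen: set[str] = set()
        for r in self.reactions:
            if r.id in seen:
                raise FormatError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            for m in r.stoich:
                if m not in met_set:
                    raise FormatError(
                        f"reaction {r.id!r} references undeclared "
                        f"metabolite {m!r}"
                    )
        if self.biomass_reaction_id not in seen:
            raise FormatError(
                f"biomass reaction {self.biomass_reaction_id!r} not found"
            )
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich.items():
                S[met_idx[m], j] = c
        return S

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return out


def read_metabolic_model(path: str | Path) -> MetabolicModelFile:
    """Read a metabolic model from the JSON dialect.

    Schema::

        {
          "metabolites": ["A", "B", ...],
          "reactions": [
            {"id": "R1", "stoich": {"A": -1, "B": 1},
             "lb": 0, "ub": 10, "gpr": "g1 and g2", "is_exchange": false},
            ...
          ],
          "biomass": "BIO"
        }

    ``gpr`` and ``is_exchange`` are optional (default empty / false).
    Bounds default to (-1000, 1000).
    """
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    for key in ("metabolites", "reactions", "biomass"):
        if key not in doc:
            raise FormatError(f"{path}: missing top-level key {key!r}")
    reactions = []
    for rec in doc["reactions"]:
        try:
            tree = parse_gpr(rec.get("gpr", ""))
        except GPRSyntaxError as exc:
            raise FormatError(
                f"{path}: unparseable GPR for reaction {rec.get('id')!r}: {exc}"
            ) from exc
        reactions.append(
            Reaction(
                id=rec["id"],
                stoich={m: float(c) for m, c in rec["stoich"].items()},
                lower_bound=float(rec.get("lb", -1000.0)),
                upper_bound=float(rec.get("ub", 1000.0)),
                gpr=tree,
                is_exchange=bool(rec.get("is_exchange", False)),
            )
        )
    return MetabolicModelFile(
        metabolites=list(doc["metabolites"]),
        reactions=reactions,
        biomass_reaction_id=doc["biomass"],
    )


def write_metabolic_model(model: MetabolicModelFile, path: str | Path) -> None:
    doc = {
        "metabolites": list(model.metabolites),
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoich,
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr_string(),
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
        "biomass": model.biomass_reaction_id,
    }
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_sbml_model(path: str | Path) -> MetabolicModelFile:
    """Minimal SBML-L3 (fbc) reader: species, reactions, bounds, GPRs.

    Requires ``python-libsbml``.  Only the subset needed for FBA is read;
    the biomass reaction is taken from the active fbc objective.
    """
    import libsbml  # local import: optional dependency

    def _strip(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0 and doc.getError(0).getSeverity() >= 2:
        raise FormatError(f"{path}: {doc.getError(0).getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: no model element")
    fbc = sbml_model.getPlugin("fbc")
    metabolites = [_strip(sbml_model.getSpecies(i).getId(), "M_")
                   for i in range(sbml_model.getNumSpecies())]
    boundary = {_strip(sbml_model.getSpecies(i).getId(), "M_")
                for i in range(sbml_model.getNumSpecies())
                if sbml_model.getSpecies(i).getBoundaryCondition()}

    def _param(pid: str, default: float) -> float:
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else default

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            sr = rxn.getReactant(j)
            sid = _strip(sr.getSpecies(), "M_")
            if sid not in boundary:
                stoich[sid] = stoich.get(sid, 0.0) - sr.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            sr = rxn.getProduct(j)
            sid = _strip(sr.getSpecies(), "M_")
            if sid not in boundary:
                stoich[sid] = stoich.get(sid, 0.0) + sr.getStoichiometry()
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = _param(rfbc.getLowerFluxBound(), -1000.0)
            ub = _param(rfbc.getUpperFluxBound(), 1000.0)
        else:
            lb = -1000.0 if rxn.getReversible() else 0.0
            ub = 1000.0
        gpr_tree = None
        if rfbc is not None and rfbc.getGeneProductAssociation() is not None:
            assoc = rfbc.getGeneProductAssociation().getAssociation()
            gpr_tree = _sbml_association_to_gpr(assoc, sbml_model)
        rid = _strip(rxn.getId(), "R_")
        reactions.append(
            Reaction(rid, stoich, lb, ub, gpr_tree,
                     is_exchange=rid.startswith("EX_"))
        )
    biomass = None
    if fbc is not None and fbc.getActiveObjective() is not None:
        obj = fbc.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            biomass = _strip(obj.getFluxObjective(0).getReaction(), "R_")
    if biomass is None:
        raise FormatError(f"{path}: no fbc objective to identify biomass")
    mets = [m for m in metabolites if m not in boundary]
    return MetabolicModelFile(mets, reactions, biomass)


def _sbml_association_to_gpr(assoc, sbml_model) -> GPRNode | None:
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        fbc = sbml_model.getPlugin("fbc")
        gp = fbc.getGeneProduct(assoc.getGeneProduct())
        label = gp.getLabel() if gp is not None and gp.isSetLabel() else None
        gid = label or assoc.getGeneProduct()
        return GPRNode("gene", gene=gid[2:] if gid.startswith("G_") else gid)
    if isinstance(assoc, libsbml.FbcAnd):
        kids = tuple(_sbml_association_to_gpr(assoc.getAssociation(i), sbml_model)
                     for i in range(assoc.getNumAssociations()))
        return GPRNode("and", children=kids)
    if isinstance(assoc, libsbml.FbcOr):
        kids = tuple(_sbml_association_to_gpr(assoc.getAssociation(i), sbml_model)
                     for i in range(assoc.getNumAssociations()))
        return GPRNode("or", children=kids)
    raise FormatError(f"unsupported SBML gene association node {assoc!r}")


# ---------------------------------------------------------------------------
# GO annotation


@dataclass
class GoAnnotation:
    """term -> (level, gene set) mapping plus the gene universe."""

    terms: dict[str, tuple[int, set[str]]]
    universe: set[str]

    def __post_init__(self) -> None:
        for term, (level, genes) in self.terms.items():
            if level < 1:
                raise FormatError(f"term {term!r}: level must be >= 1")
            missing = genes - self.universe
            if missing:
                raise FormatError(
                    f"term {term!r}: genes outside universe: {sorted(missing)[:5]}"
                )


def read_go_annotation(path: str | Path,
                       universe: Iterable[str] | None = None) -> GoAnnotation:
    """Read a ``term_id  level  gene_id`` TSV (one gene per row)."""
    path = Path(path)
    terms: dict[str, tuple[int, set[str]]] = {}
    seen_genes: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            term, level_s, gene = (p.strip() for p in parts)
            if lineno == 1 and term == "term_id":
                continue
            try:
                level = int(level_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer level {level_s!r}"
                ) from None
            prev = terms.get(term)
            if prev is not None and prev[0] != level:
                raise FormatError(
                    f"{path}:{lineno}: conflicting levels for term {term!r}"
                )
            terms.setdefault(term, (level, set()))[1].add(gene)
            seen_genes.add(gene)
    uni = set(universe) if universe is not None else seen_genes
    return GoAnnotation(terms, uni | seen_genes)


def write_go_annotation(annotation: GoAnnotation, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("term_id\tlevel\tgene_id\n")
        for term in sorted(annotation.terms):
            level, genes = annotation.terms[term]
            for g in sorted(genes):
                fh.write(f"{term}\t{level}\t{g}\n")


# ---------------------------------------------------------------------------
# Trained-model serialization (thin wrappers; the dataclass owns the codec)


def save_regulatory_model(model, path: str | Path) -> None:
    from .transcriptional import RegulatoryModel  # noqa: F401  (type check)

    with Path(path).open("w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_regulatory_model(path: str | Path):
    from .transcriptional import RegulatoryModel

    with Path(path).open() as fh:
        return RegulatoryModel.from_dict(json.load(fh))
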