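"""Signal transduction: effector changes -> TF expression/activity constraints.

Two effector mechanisms are modeled.  Expression-type systems shift the
TF's expression linearly with the effector concentration change,

    y_tf = clamp(y_wt_tf + omega * kappa * delta_n, y_min_tf, y_max_tf),

where kappa's sign encodes whether the effector raises or lowers TF
concentration and omega is a single global tuning scale.  Activity-type
systems instead switch the TF's regulatory function off (a binary
functionality variable); downstream, an inactive TF has its coefficient
column zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .transcriptional import RegulatoryModel

EXPRESSION_TYPES = ("I", "II", "III", "IV")


class SignalError(ValueError):
    pass


@dataclass(frozen=True)
class SignalEntry:
    tf_id: str
    effector_id: str
    type: str                       # I..IV or "activity_only"
    kappa: float = 0.0              # log2-expression per unit effector change
    functional_with_effector: bool | None = None  # activity_only entries only

    def __post_init__(self) -> None:
        if self.type not in EXPRESSION_TYPES + ("activity_only",):
            raise SignalError(f"unknown system type {self.type!r}")
        if self.type == "activity_only":
            if self.functional_with_effector is None:
                raise SignalError(
                    f"activity_only entry ({self.tf_id}, {self.effector_id}) "
                    "needs functional_with_effector"
                )
        elif not np.isfinite(self.kappa):
            raise SignalError(
                f"non-finite kappa for ({self.tf_id}, {self.effector_id})"
            )

    @property
    def is_activity_only(self) -> bool:
        return self.type == "activity_only"


@dataclass
class SignalSystem:
    """Collection of (TF, effector) entries plus the global omega scale."""

    entries: list[SignalEntry] = field(default_factory=list)
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise SignalError("omega must be positive")
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.tf_id, e.effector_id)
            if key in seen:
                raise SignalError(f"duplicate entry for {key}")
            seen.add(key)
        self._by_pair = {(e.tf_id, e.effector_id): e for e in self.entries}

    def effector_ids(self) -> set[str]:
        return {e.effector_id for e in self.entries}

    def entry(self, tf: str, effector: str) -> SignalEntry | None:
        return self._by_pair.get((tf, effector))

    def entries_for_effector(self, effector: str) -> list[SignalEntry]:
        return [e for e in self.entries if e.effector_id == effector]


def read_sts(path: str | Path, omega: float = 1.0) -> SignalSystem:
    """Read the STS TSV: columns ``tf  effector  type  kappa_or_brule``.

    For activity-only rows the 4th column is ``functional`` or
    ``nonfunctional`` (TF state when the effector is present).
    """
    entries = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 4:
                raise SignalError(f"{path}:{lineno}: expected 4 columns")
            tf, eff, typ, last = parts
            if lineno == 1 and tf == "tf":
                continue
            if typ == "activity_only":
                if last not in ("functional", "nonfunctional"):
                    raise SignalError(
                        f"{path}:{lineno}: activity rule must be "
                        "'functional' or 'nonfunctional'"
                    )
                entries.append(SignalEntry(
                    tf, eff, typ,
                    functional_with_effector=(last == "functional"),
                ))
            else:
                try:
                    kappa = float(last)
                except ValueError:
                    raise SignalError(
                        f"{path}:{lineno}: non-numeric kappa {last!r}"
                    ) from None
                entries.append(SignalEntry(tf, eff, typ, kappa=kappa))
    return SignalSystem(entries, omega=omega)


def write_sts(system: SignalSystem, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("tf\teffector\ttype\tkappa_or_brule\n")
        for e in system.entries:
            if e.is_activity_only:
                last = ("functional" if e.functional_with_effector
                        else "nonfunctional")
            else:
                last = repr(e.kappa)
            fh.write(f"{e.tf_id}\t{e.effector_id}\t{e.type}\t{last}\n")


def tf_expression_constraint(system: SignalSystem, model: RegulatoryModel,
                             tf: str, effector: str,
                             delta_n: float) -> float:
    """Fixed expression value for a TF under an effector concentration shift."""
    entry = system.entry(tf, effector)
    if entry is None:
        known = sorted({e.effector_id for e in system.entries
                        if e.tf_id == tf})
        raise SignalError(
            f"no signal entry for TF {tf!r} and effector {effector!r}; "
            f"known effectors for this TF: {known or 'none'}"
        )
    if entry.is_activity_only:
        raise SignalError(
            f"({tf}, {effector}) is an activity-only system; it constrains "
            "functionality, not expression"
        )
    i = model.index(tf)
    raw = model.y_wt[i] + system.omega * entry.kappa * delta_n
    return float(np.clip(raw, model.y_min[i], model.y_max[i]))


def tf_functionality(system: SignalSystem, tf: str, effector: str,
                     effector_present: bool) -> int:
    """Binary functionality of a TF under an activity-type effector."""
    entry = system.entry(tf, effector)
    if entry is None:
        raise SignalError(f"no signal entry for ({tf!r}, {effector!r})")
    if not entry.is_activity_only:
        raise SignalError(
            f"({tf}, {effector}) is an expression-type system "
            f"(type {entry.type}); functionality is not defined for it"
        )
    if effector_present:
        return 1 if entry.functional_with_effector else 0
    return 0 if entry.functional_with_effector else 1


def environment_to_constraints(
    system: SignalSystem, model: RegulatoryModel,
    environment: Sequence[tuple[str, float]] | Iterable[tuple[str, float]],
) -> tuple[dict[str, float], set[str]]:
    """Translate effector deltas into (fixed TF expression map, inactive TFs).

    A TF hit by several expression-type effectors accumulates their
    ``omega * kappa * delta`` shifts additively before a single clamp.  An
    activity-type effector with nonzero delta counts as "present" and may
    switch its TF off.
    """
    environment = list(environment)
    known = system.effector_ids()
    for eff, _ in environment:
        if eff not in known:
            raise SignalError(
                f"unknown effector {eff!r}; known effectors: {sorted(known)}"
            )
    shifts: dict[str, float] = {}
    inactive: set[str] = set()
    for eff, delta in environment:
        for entry in system.entries_for_effector(eff):
            if entry.is_activity_only:
                present = delta != 0
                if tf_functionality(system, entry.tf_id, eff, present) == 0:
                    inactive.add(entry.tf_id)
            else:
                shifts[entry.tf_id] = (
                    shifts.get(entry.tf_id, 0.0)
                    + system.omega * entry.kappa * delta
                )
    fixed: dict[str, float] = {}
    for tf, shift in shifts.items():
        i = model.index(tf)
        fixed[tf] = float(np.clip(model.y_wt[i] + shift,
                                  model.y_min[i], model.y_max[i]))
    return fixed, inactive
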