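"""Threshold gates over event features and per-cartridge enumeration.

A gate is a conjunction of threshold predicates on the feature table produced
by :func:`ctcev.pipeline.extract_objects`.  The default CTC gate is

    mean_cd45 <= 5, mean_dna > 45, mean_ck > 60, mean_marker1 <= 5,
    mean_marker2 <= 5, 16 <= size_ck <= 400, dna_overlay_ck > 0.2

i.e. a cytokeratin-positive, nucleated, CD45-negative object between roughly
3.6 and 18 um equivalent diameter at 0.67 um/pixel.  The default tdEV gate
keeps the CK/CD45/marker predicates but requires the *absence* of a nucleus
(low DNA or low DNA-on-CK overlay) and admits smaller particles; its
thresholds are provisional and fully configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class GateSchemaError(KeyError):
    """A predicate references a feature that does not exist."""


class DegenerateFitError(ValueError):
    """Regression input with zero variance."""


_OPS = {
    "le": lambda v, t: v <= t,
    "lt": lambda v, t: v < t,
    "ge": lambda v, t: v >= t,
    "gt": lambda v, t: v > t,
}


@dataclass(frozen=True)
class Predicate:
    """One threshold predicate: ``feature <op> value``.

    ``op`` is one of ``le, lt, ge, gt, between``; ``between`` is the closed
    interval and takes ``value = (low, high)`` with ``low <= high``.
    """

    feature: str
    op: str
    value: object

    def __post_init__(self):
        if self.op == "between":
            lo, hi = self.value
            if lo > hi:
                raise ValueError(f"between({self.feature}): low > high")
        elif self.op not in _OPS:
            raise ValueError(f"unknown comparator {self.op!r}")

    def evaluate(self, features) -> "np.ndarray | bool":
        try:
            v = features[self.feature]
        except KeyError:
            raise GateSchemaError(f"unknown feature {self.feature!r}") from None
        if self.op == "between":
            lo, hi = self.value
            return (v >= lo) & (v <= hi)
        return _OPS[self.op](v, self.value)

    def to_dict(self) -> dict:
        value = list(self.value) if self.op == "between" else self.value
        return {"feature": self.feature, "op": self.op, "value": value}


@dataclass(frozen=True)
class AnyOf:
    """Disjunction of predicates (used e.g. for "not nucleated")."""

    predicates: tuple

    def evaluate(self, features):
        out = None
        for p in self.predicates:
            r = p.evaluate(features)
            out = r if out is None else (out | r)
        return out

    def to_dict(self) -> dict:
        return {"any_of": [p.to_dict() for p in self.predicates]}


def _clause_from_dict(d: dict):
    if "any_of" in d:
        return AnyOf(tuple(Predicate(**p) for p in d["any_of"]))
    value = d["value"]
    if d["op"] == "between":
        value = tuple(value)
    return Predicate(d["feature"], d["op"], value)


@dataclass(frozen=True)
class GateDefinition:
    """Named conjunction of predicates / disjunctive clauses."""

    name: str
    clauses: tuple

    def evaluate(self, features):
        """Vectorized over a DataFrame (returns a boolean Series) or a single
        event given as a mapping (returns a bool)."""
        out = None
        for clause in self.clauses:
            r = clause.evaluate(features)
            out = r if out is None else (out & r)
        if out is None:
            n = len(features) if isinstance(features, pd.DataFrame) else 1
            out = pd.Series(True, index=features.index) if isinstance(features, pd.DataFrame) else True
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "clauses": [c.to_dict() for c in self.clauses]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GateDefinition":
        d = json.loads(text)
        return cls(d["name"], tuple(_clause_from_dict(c) for c in d["clauses"]))


def ctc_gate() -> GateDefinition:
    """The quantitative CTC gate (intensity units on the image scale)."""
    return GateDefinition(
        "ctc",
        (
            Predicate("mean_cd45", "le", 5.0),
            Predicate("mean_dna", "gt", 45.0),
            Predicate("mean_ck", "gt", 60.0),
            Predicate("mean_marker1", "le", 5.0),
            Predicate("mean_marker2", "le", 5.0),
            Predicate("size_ck", "between", (16.0, 400.0)),
            Predicate("dna_overlay_ck", "gt", 0.2),
        ),
    )


def tdev_gate(size_low: float = 3.0, size_high: float = 400.0) -> GateDefinition:
    """Default tdEV gate: CK-positive, CD45-negative, *not* nucleated.

    "Not nucleated" is the complement of the CTC gate's nuclear requirement:
    mean DNA <= 45 or DNA-on-CK overlay <= 0.2.  The size interval is
    provisional and configurable.
    """
    return GateDefinition(
        "tdev",
        (
            Predicate("mean_cd45", "le", 5.0),
            Predicate("mean_ck", "gt", 60.0),
            Predicate("mean_marker1", "le", 5.0),
            Predicate("mean_marker2", "le", 5.0),
            Predicate("size_ck", "between", (size_low, size_high)),
            AnyOf(
                (
                    Predicate("mean_dna", "le", 45.0),
                    Predicate("dna_overlay_ck", "le", 0.2),
                )
            ),
        ),
    )


def apply_gate(event, gate: GateDefinition) -> bool:
    """True iff every predicate of ``gate`` holds for one event (a mapping or
    a single DataFrame row)."""
    if isinstance(event, pd.Series):
        event = event.to_dict()
    return bool(gate.evaluate(event))


@dataclass
class EnumerationResult:
    """Per-cartridge enumeration with auditable per-event flags."""

    cartridge_id: str
    n_objects_total: int
    n_ctc: int
    n_tdev: int
    flags: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cartridge_id": self.cartridge_id,
                    "n_objects_total": self.n_objects_total,
                    "n_ctc": self.n_ctc,
                    "n_tdev": self.n_tdev,
                }
            ]
        )


def enumerate_cartridge(
    events: pd.DataFrame,
    ctc: GateDefinition | None = None,
    tdev: GateDefinition | None = None,
    cartridge_id: str = "cartridge",
) -> EnumerationResult:
    """Count events passing the CTC and tdEV gates.

    Returns the totals plus a per-event membership table (``event``,
    ``is_ctc``, ``is_tdev``) so the funnel from objects to gated events can
    be audited.
    """
    ctc = ctc or ctc_gate()
    tdev = tdev or tdev_gate()
    if len(events) == 0:
        flags = pd.DataFrame(columns=["event", "is_ctc", "is_tdev"])
        return EnumerationResult(cartridge_id, 0, 0, 0, flags)
    is_ctc = np.asarray(ctc.evaluate(events), dtype=bool)
    is_tdev = np.asarray(tdev.evaluate(events), dtype=bool)
    flags = pd.DataFrame(
        {
            "event": events["event"].to_numpy() if "event" in events else np.arange(len(events)),
            "is_ctc": is_ctc,
            "is_tdev": is_tdev,
        }
    )
    return EnumerationResult(
        cartridge_id=cartridge_id,
        n_objects_total=int(len(events)),
        n_ctc=int(is_ctc.sum()),
        n_tdev=int(is_tdev.sum()),
        flags=flags,
    )


def compare_counts(manual, automated):
    """OLS regression of automated counts on manual counts.

    Returns ``(slope, intercept, r_squared)``; requires >= 3 pairs and
    non-constant manual counts.
    """
    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if manual.shape != automated.shape or manual.size < 3:
        raise ValueError("need >= 3 paired counts of equal length")
    if np.var(manual) == 0:
        raise DegenerateFitError("manual counts have zero variance")
    res = stats.linregress(manual, automated)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
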