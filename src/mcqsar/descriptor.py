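"""Correlation-weight tables and the optimal descriptor DCW(T, N).

The descriptor of a molecule is the sum of the correlation weights of
its attributes,

    DCW(T, N) = sum CW(Sk) + sum CW(SSk) + CW(XYX) + CW(XYYX) + CW(XYZYX),

where T is the frequency threshold on the active training set and N the
number of Monte Carlo epochs used to tune the weights.  An attribute
seen in fewer than T active-training molecules is inactive: its weight
is pinned to zero and it contributes nothing.  Attributes never seen in
the active training set are not used at all (they contribute zero at
prediction time but are recorded for the applicability-domain defect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .attributes import MoleculeAttributes
from .errors import ConfigurationError

__all__ = ["AttributeStats", "CorrelationWeightTable", "build_vocabulary", "compute_dcw"]


@dataclass(frozen=True)
class AttributeStats:
    """Per-set molecule frequencies of one attribute.

    Frequencies count molecules containing the attribute at least once,
    not total occurrences.
    """

    n_active: int = 0
    n_passive: int = 0
    n_calibration: int = 0


@dataclass
class CorrelationWeightTable:
    """Attribute -> correlation weight map with frequencies and active flags."""

    threshold: int
    weights: dict[str, float] = field(default_factory=dict)
    stats: dict[str, AttributeStats] = field(default_factory=dict)
    active_flags: dict[str, bool] = field(default_factory=dict)
    #: molecule counts of the active, passive and calibration sets
    set_sizes: tuple[int, int, int] = (0, 0, 0)

    def weight(self, label: str) -> float:
        """Weight of an attribute; 0 for unknown or inactive attributes."""
        if not self.active_flags.get(label, False):
            return 0.0
        return self.weights.get(label, 0.0)

    def set_weight(self, label: str, value: float) -> None:
        if not self.active_flags.get(label, False):
            raise ConfigurationError(f"cannot set weight of inactive attribute {label!r}")
        self.weights[label] = float(value)

    def active_attributes(self) -> list[str]:
        """Sorted labels of all active attributes (deterministic order)."""
        return sorted(a for a, flag in self.active_flags.items() if flag)

    def copy(self) -> "CorrelationWeightTable":
        return CorrelationWeightTable(
            threshold=self.threshold,
            weights=dict(self.weights),
            stats=dict(self.stats),
            active_flags=dict(self.active_flags),
            set_sizes=self.set_sizes,
        )

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        """Serialize to a JSON document; weights at 17 significant digits."""
        rows = [
            {
                "attribute": a,
                "weight": float(repr(self.weights.get(a, 0.0))),
                "n_active": self.stats[a].n_active,
                "n_passive": self.stats[a].n_passive,
                "n_calibration": self.stats[a].n_calibration,
                "active_flag": self.active_flags[a],
            }
            for a in sorted(self.stats)
        ]
        return json.dumps(
            {
                "threshold": self.threshold,
                "set_sizes": list(self.set_sizes),
                "attributes": rows,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrelationWeightTable":
        doc = json.loads(text)
        table = cls(
            threshold=int(doc["threshold"]),
            set_sizes=tuple(doc.get("set_sizes", (0, 0, 0))),
        )
        for row in doc["attributes"]:
            a = row["attribute"]
            table.weights[a] = float(row["weight"])
            table.stats[a] = AttributeStats(
                row["n_active"], row["n_passive"], row["n_calibration"]
            )
            table.active_flags[a] = bool(row["active_flag"])
        return table


def _molecule_frequencies(molecules: Iterable[MoleculeAttributes], use_fls: bool) -> dict[str, int]:
    freq: dict[str, int] = {}
    for mol in molecules:
        for label in {a for a, _ in mol.iter_attributes(use_fls)}:
            freq[label] = freq.get(label, 0) + 1
    return freq


def build_vocabulary(
    active_set: list[MoleculeAttributes],
    passive_set: list[MoleculeAttributes],
    calibration_set: list[MoleculeAttributes],
    threshold: int = 1,
    use_fls: bool = True,
) -> CorrelationWeightTable:
    """Collect the attribute vocabulary over the three training-side sets.

    Every attribute observed in any set enters the table with its
    per-set molecule frequencies; only attributes reaching the frequency
    threshold in the active training set are flagged active.  All
    weights start at zero; the optimizer assigns initial values to the
    active ones.

    With ``use_fls=False`` the FLS count codes are left out of the
    vocabulary entirely (the descriptor then reduces to its Sk + SSk
    terms), which is the ablation used to measure what local symmetry
    adds to the model.
    """
    if not active_set:
        raise ConfigurationError("active training set is empty")
    if threshold < 1:
        raise ConfigurationError(f"threshold must be >= 1, got {threshold}")

    fa = _molecule_frequencies(active_set, use_fls)
    fp = _molecule_frequencies(passive_set, use_fls)
    fc = _molecule_frequencies(calibration_set, use_fls)

    table = CorrelationWeightTable(
        threshold=threshold,
        set_sizes=(len(active_set), len(passive_set), len(calibration_set)),
    )
    for label in sorted(set(fa) | set(fp) | set(fc)):
        na = fa.get(label, 0)
        table.stats[label] = AttributeStats(na, fp.get(label, 0), fc.get(label, 0))
        table.active_flags[label] = na >= threshold
        table.weights[label] = 0.0
    return table


def compute_dcw(
    mol: MoleculeAttributes,
    cw: CorrelationWeightTable | Mapping[str, float],
    use_fls: bool = True,
) -> float:
    """Optimal descriptor of one molecule: sum of attribute weights.

    Sk and SSk weights enter once per occurrence; each FLS count code
    enters once.  Unknown and inactive attributes contribute zero.
    ``cw`` may also be a plain label -> weight mapping (used by tests
    and by the planted-weight generator).
    """
    if isinstance(cw, CorrelationWeightTable):
        get = cw.weight
    else:
        get = lambda label: cw.get(label, 0.0)  # noqa: E731
    return float(sum(get(a) * mult for a, mult in mol.iter_attributes(use_fls)))
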