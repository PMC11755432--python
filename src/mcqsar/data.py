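"""Dataset I/O, curation, four-set splitting and synthetic data.

The modelling protocol partitions the curated compounds into four
roughly equal sets with distinct roles: the **active training** set
tunes the correlation weights, the **passive training** set checks that
the weights transfer to molecules not used in tuning, the
**calibration** set detects the onset of overtraining, and the
**validation** set is held out entirely to assess predictive potential.

Because the curated avian-toxicity table itself cannot be shipped, a
synthetic generator produces SMILES-like strings with an endpoint that
is an additive function of planted attribute weights plus Gaussian
noise; the planted truth is returned so recovery can be measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .attributes import MoleculeAttributes
from .errors import SchemaError, SplitError, TransformError

__all__ = [
    "Record",
    "SplitDataset",
    "LoadResult",
    "load_dataset",
    "deduplicate",
    "to_log_scale",
    "random_split",
    "synthesize_dataset",
]

SET_LABELS = ("A", "P", "C", "V")


@dataclass(frozen=True)
class Record:
    """One compound: identifier, SMILES line, endpoint value.

    ``logged`` flags whether the value is already on the log10 scale
    (raw values are mg/kg bw/day and must be positive).
    """

    id: str
    smiles: str
    value: float
    set_label: str | None = None
    logged: bool = False


@dataclass
class SplitDataset:
    """Records partitioned into the four protocol sets."""

    active: list[Record]
    passive: list[Record]
    calibration: list[Record]
    validation: list[Record]
    split_seed: int | None = None

    @property
    def sets(self) -> dict[str, list[Record]]:
        return {
            "A": self.active,
            "P": self.passive,
            "C": self.calibration,
            "V": self.validation,
        }

    def all_records(self) -> list[Record]:
        return self.active + self.passive + self.calibration + self.validation

    def attributes(self, set_label: str) -> list[MoleculeAttributes]:
        return [MoleculeAttributes.from_smiles(r.smiles) for r in self.sets[set_label]]

    def values(self, set_label: str) -> np.ndarray:
        return np.array([r.value for r in self.sets[set_label]], dtype=float)

    @classmethod
    def from_labels(cls, records: Iterable[Record], seed: int | None = None) -> "SplitDataset":
        """Partition records by their pre-assigned ``set_label``."""
        parts: dict[str, list[Record]] = {s: [] for s in SET_LABELS}
        for r in records:
            if r.set_label not in parts:
                raise SchemaError(f"record {r.id!r} has set label {r.set_label!r}, expected one of {SET_LABELS}")
            parts[r.set_label].append(r)
        return cls(parts["A"], parts["P"], parts["C"], parts["V"], split_seed=seed)


class LoadResult(NamedTuple):
    """Loaded records plus a report of malformed rows (never silently dropped)."""

    records: list[Record]
    errors: list[str]


def load_dataset(
    path: str | Path,
    fmt: str | None = None,
    id_col: str = "id",
    smiles_col: str = "smiles",
    value_col: str = "value",
    set_col: str | None = None,
) -> LoadResult:
    """Read records from a CSV table or a .smi line file.

    CSV needs the id/smiles/value columns (names configurable); ``.smi``
    is one SMILES per line with an optional whitespace-separated
    identifier (no value column, value is NaN).  Malformed rows are
    collected into the error report; well-formed rows load in file
    order.
    """
    path = Path(path)
    if fmt is None:
        fmt = "smi" if path.suffix == ".smi" else "csv"
    records: list[Record] = []
    errors: list[str] = []

    if fmt == "smi":
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            ident = parts[1] if len(parts) > 1 else f"mol{ln}"
            records.append(Record(id=ident, smiles=parts[0], value=math.nan))
        return LoadResult(records, errors)

    if fmt != "csv":
        raise SchemaError(f"unknown dataset format {fmt!r}")
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise SchemaError(f"{path}: empty dataset")
    for col in (id_col, smiles_col, value_col):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for i, row in df.iterrows():
        try:
            value = float(row[value_col])
        except (TypeError, ValueError):
            errors.append(f"row {i + 2}: non-numeric value {row[value_col]!r}")
            continue
        smiles = row[smiles_col]
        if not isinstance(smiles, str) or not smiles:
            errors.append(f"row {i + 2}: missing SMILES")
            continue
        label = row[set_col] if set_col and set_col in df.columns else None
        records.append(Record(id=str(row[id_col]), smiles=smiles, value=value, set_label=label))
    return LoadResult(records, errors)


def deduplicate(records: list[Record]) -> list[Record]:
    """Keep one record per unique SMILES string: the most toxic one.

    The lowest endpoint value survives (a lower no-effect level means a
    more toxic compound); the order of first occurrence is preserved.
    The key is the exact SMILES string — no canonicalization, since the
    formalism requires all SMILES to come from one generator.
    """
    best: dict[str, Record] = {}
    order: list[str] = []
    for r in records:
        if r.smiles not in best:
            best[r.smiles] = r
            order.append(r.smiles)
        elif r.value < best[r.smiles].value:
            best[r.smiles] = r
    return [best[s] for s in order]


def to_log_scale(records: list[Record]) -> list[Record]:
    """log10-transform endpoint values; refuses non-positive or re-logged values."""
    out = []
    for r in records:
        if r.logged:
            raise TransformError(f"record {r.id!r} is already on the log scale")
        if not r.value > 0:
            raise TransformError(f"record {r.id!r} has non-positive value {r.value}")
        out.append(replace(r, value=math.log10(r.value), logged=True))
    return out


def split_sizes(n: int) -> tuple[int, int, int, int]:
    """Largest-remainder sizes of the four ~25% sets (differ by <= 1)."""
    base, rem = divmod(n, 4)
    return tuple(base + (1 if i < rem else 0) for i in range(4))  # type: ignore[return-value]


def random_split(records: list[Record], seed: int) -> SplitDataset:
    """Seeded shuffle, then contiguous ~25% blocks assigned A, P, C, V."""
    n = len(records)
    if n < 8:
        raise SplitError(f"need at least 8 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = split_sizes(n)
    parts: list[list[Record]] = []
    start = 0
    for label, size in zip(SET_LABELS, sizes):
        idx = order[start : start + size]
        parts.append([replace(records[i], set_label=label) for i in idx])
        start += size
    return SplitDataset(*parts, split_seed=seed)


# -- synthetic data -------------------------------------------------------

#: atom-like tokens, roughly ordered by how common they are in pesticide SMILES
_ATOM_POOL = ("C", "c", "N", "n", "O", "S", "P", "Cl", "Br")
_RING_DIGITS = ("1", "2", "3")

#: target spread of the synthetic log-endpoint (mimics logged mg/kg bw/day)
_SIGNAL_SD = 0.8
_SIGNAL_MEAN = -0.5


def _random_smiles(rng: np.random.Generator, atoms: tuple[str, ...]) -> str:
    """One syntactically plausible SMILES-like string.

    Balanced parentheses, ring digits appearing in pairs, branches and
    double bonds only after an atom.  Plausible-looking, not
    chemically validated — the formalism only ever sees the string.
    """
    n_atoms = int(rng.integers(6, 22))
    out: list[str] = []
    depth = 0
    open_rings: list[str] = []
    prev_atom = False
    placed = 0
    while placed < n_atoms:
        if prev_atom:
            u = rng.random()
            if u < 0.14 and depth < 3:
                out.append("(")
                depth += 1
                prev_atom = False
                continue
            if u < 0.24 and depth > 0:
                out.append(")")
                depth -= 1
                prev_atom = False
                continue
            if u < 0.34:
                if open_rings and rng.random() < 0.6:
                    out.append(open_rings.pop())
                elif len(open_rings) < len(_RING_DIGITS):
                    d = _RING_DIGITS[len(open_rings)]
                    out.append(d)
                    open_rings.append(d)
                continue
            if u < 0.42:
                out.append("=")
                prev_atom = False
                continue
        out.append(str(rng.choice(atoms)))
        prev_atom = True
        placed += 1
    out.extend(")" * depth)
    while open_rings:
        out.append(open_rings.pop())
    return "".join(out)


def synthesize_dataset(
    n_molecules: int = 140,
    vocab_size: int = 9,
    n_signal_attributes: int = 10,
    noise_sd: float = 0.08,
    seed: int = 0,
) -> tuple[list[Record], dict]:
    """Generate a dataset with a planted additive attribute signal.

    The endpoint of molecule m is

        y_m = c0* + c1* * sum_a w*(a) * mult_m(a) + Normal(0, noise_sd),

    where the planted weights w* sit on ``n_signal_attributes``
    attributes drawn from those common in the generated molecules, and
    (c0*, c1*) scale the noiseless signal to mean -0.5 and SD 0.8 — the
    range of a logged mg/kg bw/day endpoint.  With the defaults the
    noise SD is 10% of the signal SD.  Returns the records (values
    already on the log scale) and the planted ground truth
    ``{"weights": ..., "c0": ..., "c1": ..., "noise_sd": ...}``.
    """
    rng = np.random.default_rng(seed)
    atoms = _ATOM_POOL[: max(1, min(vocab_size, len(_ATOM_POOL)))]
    smiles = [_random_smiles(rng, atoms) for _ in range(n_molecules)]
    mols = [MoleculeAttributes.from_smiles(s) for s in smiles]

    # candidate signal attributes: present in >= 20% of molecules so the
    # signal is learnable from a quarter-sized training set
    freq: dict[str, int] = {}
    for mol in mols:
        for a in {lab for lab, _ in mol.iter_attributes()}:
            freq[a] = freq.get(a, 0) + 1
    common = sorted(a for a, k in freq.items() if k >= 0.2 * n_molecules)
    k = min(n_signal_attributes, len(common))
    chosen = list(rng.choice(common, size=k, replace=False))
    planted = {a: float(w) for a, w in zip(chosen, rng.normal(0.0, 1.0, size=k))}

    signal = np.array(
        [sum(planted.get(a, 0.0) * m for a, m in mol.iter_attributes()) for mol in mols]
    )
    sd = signal.std()
    c1 = _SIGNAL_SD / sd if sd > 0 else 1.0
    c0 = _SIGNAL_MEAN - c1 * signal.mean()
    y = c0 + c1 * signal + rng.normal(0.0, noise_sd, size=n_molecules)

    records = [
        Record(id=f"syn{i:04d}", smiles=s, value=float(v), logged=True)
        for i, (s, v) in enumerate(zip(smiles, y))
    ]
    truth = {"weights": planted, "c0": float(c0), "c1": float(c1), "noise_sd": noise_sd}
    return records, truth
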