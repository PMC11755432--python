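"""Published reference fixtures shipped with the package.

``dcw_worked_example.tsv`` is the 66-row correlation-weight listing of
the worked-example pesticide from the original avian-toxicity model
release: one row per attribute occurrence (32 SMILES atoms, 31 adjacent
pairs, 3 FLS count codes) with the tuned weight and the per-set
molecule frequencies.  Summing the weight column is the reference DCW
calculation (value 16.10 at two decimals); it exercises the descriptor
summation independently of the tokenizer.
"""

from __future__ import annotations

from collections import Counter
from importlib import resources

from .attributes import MoleculeAttributes
from .descriptor import AttributeStats, CorrelationWeightTable

__all__ = ["load_worked_example"]

#: active / passive / calibration molecule counts of the split the
#: worked example was tuned on
_WORKED_EXAMPLE_SET_SIZES = (35, 33, 35)


def load_worked_example() -> tuple[MoleculeAttributes, CorrelationWeightTable]:
    """The worked-example molecule's attributes and its weight table."""
    text = (
        resources.files("mcqsar").joinpath("data/dcw_worked_example.tsv").read_text()
    )
    sk: Counter = Counter()
    ssk: Counter = Counter()
    fls: list[str] = []
    table = CorrelationWeightTable(threshold=1, set_sizes=_WORKED_EXAMPLE_SET_SIZES)
    for line in text.splitlines()[1:]:
        family, attr, weight, na, np_, nc = line.split("\t")
        if family == "sk":
            sk[attr] += 1
        elif family == "ssk":
            ssk[attr] += 1
        else:
            fls.append(attr)
        table.weights[attr] = float(weight)
        table.stats[attr] = AttributeStats(int(na), int(np_), int(nc))
        table.active_flags[attr] = True
    mol = MoleculeAttributes(sk=sk, ssk=ssk, fls=tuple(fls))
    return mol, table
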