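"""Final regression model, interpretation and applicability domain.

Once the correlation weights are tuned, the endpoint is modelled by an
ordinary least-squares line in the descriptor,

    LTT = C0 + C1 * DCW(T, N),

with coefficient standard errors reported in the usual "(+/- ...)"
style.  Interpretation classifies every active attribute over several
independent optimization runs: a weight that stays positive in every
run marks a promoter of endpoint increase, consistently negative marks
a promoter of decrease, and a sign change marks the attribute as
unstable.

The applicability domain rests on the statistical defect of a SMILES:
for attribute A with fractions P(A) and P'(A) of active-training and
calibration molecules containing it,

    d(A) = |P(A) - P'(A)| / (P(A) + P'(A))        (0 when both are 0),

and the defect of a molecule is the sum of d(A) over its attributes
with multiplicity.  A molecule whose defect exceeds twice the mean
defect of the active training set is outside the domain.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .attributes import MoleculeAttributes
from .descriptor import CorrelationWeightTable, compute_dcw
from .data import SplitDataset
from .errors import ConfigurationError, DegenerateFitError
from .metrics import SetStatistics, determination, error_stats, panel
from .optimizer import OptimizationConfig, OptimizationTrace, optimize

__all__ = [
    "QsarModel",
    "PromoterReport",
    "DomainAssessment",
    "fit_regression",
    "fit_model",
    "predict",
    "evaluate",
    "promoter_analysis",
    "applicability_domain",
]

#: multiplier on the mean active-set defect that bounds the domain
DEFECT_CUTOFF_FACTOR = 2.0


def fit_regression(dcw, endpoint) -> tuple[float, float, float, float]:
    """OLS fit of endpoint on descriptor: (c0, c1, c0_se, c1_se)."""
    x = np.asarray(dcw, dtype=float)
    y = np.asarray(endpoint, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateFitError(f"need at least 3 points, got {n}")
    xd = x - x.mean()
    sxx = float((xd * xd).sum())
    if sxx == 0.0:
        raise DegenerateFitError("descriptor is constant; slope undefined")
    c1 = float((xd * (y - y.mean())).sum() / sxx)
    c0 = float(y.mean() - c1 * x.mean())
    resid = y - (c0 + c1 * x)
    s2 = float((resid * resid).sum() / (n - 2)) if n > 2 else 0.0
    c1_se = float(np.sqrt(s2 / sxx))
    c0_se = float(np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)))
    return c0, c1, c0_se, c1_se


@dataclass
class QsarModel:
    """Correlation-weight table + regression line + run configuration."""

    cw: CorrelationWeightTable
    c0: float
    c1: float
    c0_se: float
    c1_se: float
    config: OptimizationConfig
    defect_threshold: float = float("inf")
    defect_cutoff_factor: float = DEFECT_CUTOFF_FACTOR

    def dcw(self, smiles: str) -> float:
        return compute_dcw(
            MoleculeAttributes.from_smiles(smiles), self.cw, use_fls=self.config.use_fls
        )

    def equation(self) -> str:
        """The fitted line in the conventional (+/-) notation."""
        return (
            f"LTT = {self.c0:.3f}(+/-{self.c0_se:.3f}) "
            f"+ {self.c1:.4f}(+/-{self.c1_se:.4f}) * "
            f"DCW({self.config.threshold},{self.config.epochs})"
        )

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "rng": "numpy.random.default_rng (PCG64)",
            "c0": self.c0,
            "c1": self.c1,
            "c0_se": self.c0_se,
            "c1_se": self.c1_se,
            "defect_threshold": self.defect_threshold,
            "defect_cutoff_factor": self.defect_cutoff_factor,
            "config": asdict(self.config),
            "weights": json.loads(self.cw.to_json()),
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QsarModel":
        doc = json.loads(text)
        return cls(
            cw=CorrelationWeightTable.from_json(json.dumps(doc["weights"])),
            c0=doc["c0"],
            c1=doc["c1"],
            c0_se=doc["c0_se"],
            c1_se=doc["c1_se"],
            config=OptimizationConfig(**doc["config"]),
            defect_threshold=doc["defect_threshold"],
            defect_cutoff_factor=doc.get("defect_cutoff_factor", DEFECT_CUTOFF_FACTOR),
        )


def fit_model(
    split: SplitDataset, cfg: OptimizationConfig
) -> tuple[QsarModel, OptimizationTrace]:
    """Optimize correlation weights on a split and fit the final line."""
    table, trace = optimize(split, cfg)
    mols_a = split.attributes("A")
    dcw_a = np.array([compute_dcw(m, table, cfg.use_fls) for m in mols_a])
    c0, c1, c0_se, c1_se = fit_regression(dcw_a, split.values("A"))
    model = QsarModel(cw=table, c0=c0, c1=c1, c0_se=c0_se, c1_se=c1_se, config=cfg)
    # domain cutoff from the active-training defect distribution
    defects = [_molecule_defect(m, table, cfg.use_fls) for m in mols_a]
    model.defect_threshold = model.defect_cutoff_factor * float(np.mean(defects))
    return model, trace


def predict(model: QsarModel, smiles: str) -> float:
    """Endpoint prediction C0 + C1 * DCW; unknown attributes contribute 0."""
    return model.c0 + model.c1 * model.dcw(smiles)


def predict_table(model: QsarModel, records) -> pd.DataFrame:
    """Predictions for many records: id, smiles, dcw, prediction, defect, in_domain."""
    rows = []
    for r in records:
        mol = MoleculeAttributes.from_smiles(r.smiles)
        dcw = compute_dcw(mol, model.cw, model.config.use_fls)
        defect = _molecule_defect(mol, model.cw, model.config.use_fls)
        rows.append(
            {
                "id": r.id,
                "smiles": r.smiles,
                "dcw": dcw,
                "prediction": model.c0 + model.c1 * dcw,
                "defect": defect,
                "in_domain": bool(defect < model.defect_threshold),
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "smiles", "dcw", "prediction", "defect", "in_domain"]
    )


def evaluate(
    model: QsarModel, split: SplitDataset, full_panel: bool = False
) -> dict[str, SetStatistics]:
    """Quality panel per set.

    The validation set reports only R2, RMSE and MAE by convention (it
    plays no role during model development, so the development-side
    indices are withheld); ``full_panel=True`` unlocks the rest.
    Empty sets are skipped.
    """
    out: dict[str, SetStatistics] = {}
    for label, recs in split.sets.items():
        if not recs:
            continue
        obs = split.values(label)
        dcw = np.array(
            [compute_dcw(m, model.cw, model.config.use_fls) for m in split.attributes(label)]
        )
        pred = model.c0 + model.c1 * dcw
        if label == "V" and not full_panel:
            r2 = determination(obs, pred)
            rmse, mae = error_stats(obs, pred)
            out[label] = SetStatistics(
                n=len(recs), r2=r2, ccc=np.nan, iic=np.nan, cii=np.nan,
                q2=np.nan, rmse=rmse, mae=mae, f=np.nan,
            )
        else:
            out[label] = panel(obs, pred, dcw=dcw)
    return out


def stats_tsv(stats: dict[str, SetStatistics]) -> str:
    """Render per-set panels as a TSV report (F rounded to integer)."""
    cols = ["set", "n", "r2", "ccc", "iic", "cii", "q2", "rmse", "mae", "f"]
    lines = ["\t".join(cols)]
    for label in ("A", "P", "C", "V"):
        if label not in stats:
            continue
        s = stats[label]
        def fmt(v, ndig=4):
            return "-" if v != v else f"{v:.{ndig}f}"  # NaN renders as a dash
        f_str = "-" if s.f != s.f else str(round(s.f))
        lines.append(
            "\t".join(
                [label, str(s.n), fmt(s.r2), fmt(s.ccc), fmt(s.iic), fmt(s.cii),
                 fmt(s.q2), fmt(s.rmse, 3), fmt(s.mae, 3), f_str]
            )
        )
    return "\n".join(lines) + "\n"


# -- interpretation -------------------------------------------------------


@dataclass
class PromoterReport:
    """Per-attribute weights across runs and stability classification."""

    n_runs: int
    rows: list[dict] = field(default_factory=list)  # attribute, weights, class, na/np/nc

    def to_tsv(self) -> str:
        header = ["attribute"] + [str(i + 1) for i in range(self.n_runs)] + [
            "class", "n_active", "n_passive", "n_calibration",
        ]
        lines = ["\t".join(header)]
        for row in self.rows:
            lines.append(
                "\t".join(
                    [row["attribute"]]
                    + [f"{w:.4f}" for w in row["weights"]]
                    + [row["class"], str(row["n_active"]),
                       str(row["n_passive"]), str(row["n_calibration"])]
                )
            )
        return "\n".join(lines) + "\n"


def promoter_analysis(runs: list[CorrelationWeightTable]) -> PromoterReport:
    """Classify each active attribute over independent optimization runs.

    increase-promoter: weight > 0 in every run; decrease-promoter:
    weight < 0 in every run; otherwise unstable.  Rows sort by
    active-training frequency, descending.
    """
    if len(runs) < 2:
        raise ConfigurationError("promoter analysis needs at least 2 runs")
    vocab = runs[0].active_attributes()
    for t in runs[1:]:
        if t.active_attributes() != vocab:
            raise ConfigurationError("runs have mismatched vocabularies")
    report = PromoterReport(n_runs=len(runs))
    for a in vocab:
        ws = [t.weight(a) for t in runs]
        if all(w > 0 for w in ws):
            cls = "increase-promoter"
        elif all(w < 0 for w in ws):
            cls = "decrease-promoter"
        else:
            cls = "unstable"
        st = runs[0].stats[a]
        report.rows.append(
            {
                "attribute": a,
                "weights": ws,
                "class": cls,
                "n_active": st.n_active,
                "n_passive": st.n_passive,
                "n_calibration": st.n_calibration,
            }
        )
    report.rows.sort(key=lambda r: (-r["n_active"], r["attribute"]))
    return report


# -- applicability domain -------------------------------------------------


@dataclass
class DomainAssessment:
    ids: list[str]
    defects: list[float]
    in_domain: list[bool]
    threshold: float

    @property
    def n_outliers(self) -> int:
        return sum(not flag for flag in self.in_domain)


def _molecule_defect(
    mol: MoleculeAttributes,
    table: CorrelationWeightTable,
    use_fls: bool = True,
) -> float:
    na_tot, _, nc_tot = table.set_sizes
    total = 0.0
    for a, mult in mol.iter_attributes(use_fls):
        st = table.stats.get(a)
        if st is None:
            total += 1.0 * mult  # unseen attribute: maximal defect
            continue
        p = st.n_active / na_tot if na_tot else 0.0
        q = st.n_calibration / nc_tot if nc_tot else 0.0
        if p + q > 0:
            total += mult * abs(p - q) / (p + q)
    return total


def applicability_domain(
    model: QsarModel,
    molecules: list[MoleculeAttributes],
    ids: list[str] | None = None,
) -> DomainAssessment:
    """Statistical-defect domain assessment for a list of molecules."""
    ids = ids or [str(i) for i in range(len(molecules))]
    defects = [
        _molecule_defect(m, model.cw, model.config.use_fls) for m in molecules
    ]
    flags = [d < model.defect_threshold for d in defects]
    return DomainAssessment(
        ids=list(ids), defects=defects, in_domain=flags, threshold=model.defect_threshold
    )
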