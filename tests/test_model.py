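"""Final regression, prediction, promoters and applicability domain."""

import numpy as np
import pytest

from mcqsar.attributes import MoleculeAttributes
from mcqsar.descriptor import build_vocabulary
from mcqsar.errors import ConfigurationError, DegenerateFitError
from mcqsar.model import (
    QsarModel,
    applicability_domain,
    evaluate,
    fit_model,
    fit_regression,
    predict,
    predict_table,
    promoter_analysis,
    stats_tsv,
)
from mcqsar.optimizer import OptimizationConfig
from mcqsar.reference import load_worked_example


def test_fit_regression_exact_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    c0, c1, se0, se1 = fit_regression(x, 2 * x + 1)
    assert (c0, c1) == pytest.approx((1.0, 2.0))
    assert se0 == pytest.approx(0.0, abs=1e-12)
    assert se1 == pytest.approx(0.0, abs=1e-12)


def test_fit_regression_matches_closed_form(rng):
    x = rng.normal(size=25)
    y = 1.5 * x - 0.3 + rng.normal(scale=0.4, size=25)
    c0, c1, se0, se1 = fit_regression(x, y)
    # independent oracle: textbook OLS with standard errors
    n = x.size
    b1 = np.cov(x, y, bias=True)[0, 1] / x.var()
    b0 = y.mean() - b1 * x.mean()
    resid = y - b0 - b1 * x
    s2 = (resid**2).sum() / (n - 2)
    sxx = ((x - x.mean()) ** 2).sum()
    assert c1 == pytest.approx(b1, abs=1e-12)
    assert c0 == pytest.approx(b0, abs=1e-12)
    assert se1 == pytest.approx(np.sqrt(s2 / sxx), abs=1e-12)
    assert se0 == pytest.approx(np.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx)), abs=1e-12)


def test_fit_regression_degenerate():
    with pytest.raises(DegenerateFitError):
        fit_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def _worked_example_model():
    _, table = load_worked_example()
    cfg = OptimizationConfig(seed=0)
    return QsarModel(
        cw=table, c0=-1.949, c1=0.1307, c0_se=0.019, c1_se=0.0023,
        config=cfg, defect_threshold=1.0,
    )


def test_predict_is_affine_in_dcw():
    """Prediction with the reference regression coefficients on a DCW
    of 16.10 lands at -1.949 + 0.1307 * 16.10 ~= 0.155."""
    model = _worked_example_model()
    mol, table = load_worked_example()
    dcw = sum(table.weights[a] * m for a, m in mol.iter_attributes())
    assert model.c0 + model.c1 * dcw == pytest.approx(0.155, abs=5e-3)


def test_predict_unknown_molecule_gets_intercept():
    model = _worked_example_model()
    # no attribute overlap: unknown atoms/pairs AND FLS counts (0, 1, 0)
    # that miss the table's [xyx7]/[xyyx0]/[xyzyx1] codes
    assert predict(model, "brrb") == pytest.approx(model.c0 + model.c1 * 0.0)


def test_predict_deterministic():
    model = _worked_example_model()
    s = "O=C(O)c1nc(c(c(N)c1Cl)Cl)Cl"
    assert predict(model, s) == predict(model, s)


def test_equation_rendering():
    model = _worked_example_model()
    text = model.equation()
    assert "(+/-" in text and "DCW(1,15)" in text


def test_model_json_round_trip(small_split, quick_config):
    model, _ = fit_model(small_split, quick_config)
    clone = QsarModel.from_json(model.to_json())
    assert clone.c0 == model.c0 and clone.c1 == model.c1
    assert clone.cw.weights == model.cw.weights
    assert clone.config == model.config
    assert clone.defect_threshold == model.defect_threshold


def test_evaluate_panel_composition(small_split, quick_config):
    model, _ = fit_model(small_split, quick_config)
    stats = evaluate(model, small_split)
    assert set(stats) == {"A", "P", "C", "V"}
    for label in ("A", "P", "C"):
        s = stats[label]
        assert s.mae <= s.rmse + 1e-12
        assert 0.0 <= s.r2 <= 1.0
    # validation row reports only r2 / rmse / mae by default
    v = stats["V"]
    assert np.isnan(v.ccc) and np.isnan(v.q2) and np.isnan(v.f)
    assert not np.isnan(v.r2)
    full = evaluate(model, small_split, full_panel=True)
    assert not np.isnan(full["V"].ccc)


def test_stats_tsv_layout(small_split, quick_config):
    model, _ = fit_model(small_split, quick_config)
    text = stats_tsv(evaluate(model, small_split))
    lines = text.strip().splitlines()
    assert lines[0].split("\t") == ["set", "n", "r2", "ccc", "iic", "cii", "q2", "rmse", "mae", "f"]
    assert len(lines) == 5
    assert lines[4].split("\t")[3] == "-"  # V row dashes


def test_promoter_classification_rules(small_split, quick_config):
    from mcqsar.optimizer import multi_run

    runs = multi_run(small_split, quick_config, n_runs=2)
    report = promoter_analysis(runs)
    classes = {r["attribute"]: r["class"] for r in report.rows}
    for row in report.rows:
        ws = row["weights"]
        if all(w > 0 for w in ws):
            assert row["class"] == "increase-promoter"
        elif all(w < 0 for w in ws):
            assert row["class"] == "decrease-promoter"
        else:
            assert row["class"] == "unstable"
    # partition of the active vocabulary, sorted by active frequency
    assert sorted(classes) == runs[0].active_attributes()
    freqs = [r["n_active"] for r in report.rows]
    assert freqs == sorted(freqs, reverse=True)


def test_promoter_published_example():
    """Weights staying positive across five runs mark an increase promoter
    (the published [xyyx0] row behaves this way)."""
    _, table = load_worked_example()
    runs = []
    for w in (1.1230, 0.9561, 1.0716, 1.3799, 0.4717):
        t = table.copy()
        t.weights = dict(t.weights)
        t.weights["[xyyx0]"] = w
        runs.append(t)
    report = promoter_analysis(runs)
    row = next(r for r in report.rows if r["attribute"] == "[xyyx0]")
    assert row["class"] == "increase-promoter"
    assert row["weights"] == [1.1230, 0.9561, 1.0716, 1.3799, 0.4717]


def test_promoter_mismatched_vocabulary_rejected(small_split, quick_config):
    from mcqsar.optimizer import multi_run

    runs = multi_run(small_split, quick_config, n_runs=2)
    other = build_vocabulary([MoleculeAttributes.from_smiles("CC")], [], [])
    with pytest.raises(ConfigurationError):
        promoter_analysis([runs[0], other])


def test_domain_defect_rules(small_split, quick_config):
    model, _ = fit_model(small_split, quick_config)
    na, _, nc = model.cw.set_sizes
    # attribute with identical fractions in both sets contributes zero
    matched = [a for a, s in model.cw.stats.items()
               if s.n_active / na == s.n_calibration / nc and s.n_active > 0]
    only_cal = [a for a, s in model.cw.stats.items()
                if s.n_active == 0 and s.n_calibration > 0]
    from mcqsar.model import _molecule_defect

    for a in matched[:3]:
        mol = MoleculeAttributes(sk={a: 1}, ssk={}, fls=("[q0]", "[q1]", "[q2]"))
        base = MoleculeAttributes(sk={}, ssk={}, fls=("[q0]", "[q1]", "[q2]"))
        delta = _molecule_defect(mol, model.cw) - _molecule_defect(base, model.cw)
        assert delta == pytest.approx(0.0, abs=1e-12)
    for a in only_cal[:3]:
        mol = MoleculeAttributes(sk={a: 1}, ssk={}, fls=("[q0]", "[q1]", "[q2]"))
        base = MoleculeAttributes(sk={}, ssk={}, fls=("[q0]", "[q1]", "[q2]"))
        delta = _molecule_defect(mol, model.cw) - _molecule_defect(base, model.cw)
        assert delta == pytest.approx(1.0, abs=1e-12)  # maximal discrepancy


def test_domain_assessment_matches_hand_oracle(small_split, quick_config):
    model, _ = fit_model(small_split, quick_config)
    mols = small_split.attributes("V")
    assess = applicability_domain(model, mols, ids=[r.id for r in small_split.validation])
    na, _, nc = model.cw.set_sizes
    for mol, defect in zip(mols, assess.defects):
        total = 0.0
        for a, mult in mol.iter_attributes():
            st = model.cw.stats.get(a)
            if st is None:
                total += mult
                continue
            p, q = st.n_active / na, st.n_calibration / nc
            if p + q > 0:
                total += mult * abs(p - q) / (p + q)
        assert defect == pytest.approx(total, abs=1e-10)
        assert defect >= 0.0
    assert assess.n_outliers == sum(not f for f in assess.in_domain)


def test_empty_molecule_has_zero_defect(small_split, quick_config):
    model, _ = fit_model(small_split, quick_config)
    from mcqsar.model import _molecule_defect
    empty = MoleculeAttributes(sk={}, ssk={}, fls=())
    assert _molecule_defect(empty, model.cw) == 0.0


def test_predict_table_columns(small_split, quick_config):
    model, _ = fit_model(small_split, quick_config)
    df = predict_table(model, small_split.validation[:4])
    assert list(df.columns) == ["id", "smiles", "dcw", "prediction", "defect", "in_domain"]
    assert len(df) == 4
    assert np.allclose(df["prediction"], model.c0 + model.c1 * df["dcw"])
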