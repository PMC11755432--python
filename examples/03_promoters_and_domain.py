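"""Interpret a model: stable promoters and the applicability domain.

Runs several independently seeded optimizations; an attribute whose
weight keeps one sign in every run is a promoter of endpoint increase
(or decrease) — the model's mechanistic reading.  The applicability
domain flags molecules whose attribute frequencies disagree between
the active-training and calibration sets (statistical defect).
"""

from mcqsar import (
    OptimizationConfig,
    applicability_domain,
    fit_model,
    multi_run,
    promoter_analysis,
    random_split,
    synthesize_dataset,
)

records, _ = synthesize_dataset(n_molecules=80, noise_sd=0.08, seed=8)
split = random_split(records, seed=8)
cfg = OptimizationConfig(seed=8, epochs=6, restarts=2)

runs = multi_run(split, cfg, n_runs=3)
report = promoter_analysis(runs)
counts = {}
for row in report.rows:
    counts[row["class"]] = counts.get(row["class"], 0) + 1
print(f"attribute classes over {report.n_runs} runs: {counts}")
print("most frequent stable promoters (attribute, weights per run):")
for row in [r for r in report.rows if r["class"] != "unstable"][:5]:
    ws = " ".join(f"{w:+.3f}" for w in row["weights"])
    print(f"  {row['attribute']:<12} {ws}   in {row['n_active']} active molecules")

model, _ = fit_model(split, cfg)
assessment = applicability_domain(
    model, split.attributes("V"), ids=[r.id for r in split.validation]
)
print(f"\napplicability domain cutoff: defect < {assessment.threshold:.2f}")
print(f"validation outliers: {assessment.n_outliers} of {len(assessment.ids)}")
print("(a defect sums per-attribute frequency discrepancies between the "
      "active-training and calibration sets; high-defect molecules are "
      "outside what the model has evidence for)")
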