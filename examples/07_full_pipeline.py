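"""Run the whole analysis end to end.

filter multimorbid -> stratify by age -> 80/20 split -> per-stratum K
selection and fitting -> profiling -> hold-out validation -> outcome
models -> Markdown report.  All stage seeds derive from the master seed,
so a re-run is byte-identical.
"""

from mmclust import PipelineConfig, default_truth, run_pipeline, simulate_cohort

cohort, _ = simulate_cohort(default_truth(scale=20, seed=10))
cfg = PipelineConfig(
    outdir="pipeline_out",
    k_range=(1, 2, 3, 4),
    n_restarts=5,
    tol=1e-7,
    seed=11,
)
res = run_pipeline(cfg, cohort=cohort)

for label, sr in res.strata.items():
    n_agree = sum(sr.match.agreement.values()) if sr.match else 0
    n_test = len(sr.match.agreement) if sr.match else 0
    print(f"stratum {label}: K={sr.selection.chosen_K}, "
          f"reference cluster {sr.reference_cluster}, "
          f"hold-out match agreement {n_agree}/{n_test}")
print(f"\nfull report: {res.report_path}")
# Inspect pipeline_out/: per-stratum selection.csv, model.json,
# profiles/labels CSVs, match.json, GLM tables, and report.md.
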