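"""One-call reproducible pipeline run with manifest and report.

Runs aggregate -> ladder -> fit (with pruning) -> features ->
comparisons -> markers on the synthetic default cohort, then renders the
markdown report.  Re-running with the same seed gives byte-identical
artifacts (compare manifest.json checksums).
"""

from trajlens.pipeline import RunConfig, run_pipeline, summarize

cfg = RunConfig(out_dir="scratch/example_run", n_users=800, seed=7,
                n_starts=3, g_max=3, cv_folds=5)
out = run_pipeline(cfg)
print(summarize(out))
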