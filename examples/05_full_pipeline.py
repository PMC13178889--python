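"""Run the whole analysis end to end on a synthetic cohort.

Generates a cohort with a second-metatarsal pressure elevation in the
female group, extracts all parameters, runs the scalar group tests, the
spatial cluster tests at the three force peaks and two transient-phase
midpoints, and the temporal cluster tests on the five time-normalized
stance series, then renders the figure report.
"""

from pedoperm import (
    PermConfig,
    PipelineConfig,
    RegionalEffect,
    SynthCohortConfig,
    make_report,
    run_pipeline,
)

config = PipelineConfig(
    synth=SynthCohortConfig(
        n_female=10, n_male=8, seed=1,
        regional_effects=(RegionalEffect("second_metatarsal", 0.2, "female"),),
    ),
    perm=PermConfig(n_perm=200, seed=0),
    out_dir="pipeline_out",
    seed=9,
)
result = run_pipeline(config)

print(result.scalar_tests[["parameter", "t", "p", "cohens_d", "sig"]]
      .round(3).to_string(index=False))

print("\nspatial clusters (female vs male, weight-normalized pressure):")
for (side, timing), res in sorted(result.spatial.items()):
    sig = res.significant_clusters
    if sig:
        best = sig[0]
        print(f"  {side:>5} {timing:<10} {len(sig)} significant "
              f"(largest: {best.size} px, p = {best.p_corrected:.3f})")

report_dir = make_report(result)
print(f"\nfigures and summary written to {report_dir}/")

# The injected metatarsal effect shows up as a significant positive
# (female > male) cluster at the forefoot-loaded timings on both feet,
# while the scalar gait parameters reflect only the configured sex
# differences in step timing.
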