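"""Full in-silico study: cohort, four clustering approaches, biopsy report.

Runs the end-to-end pipeline on the 6-patient synthetic cohort (44
biopsies, 2 excluded for low cellularity) and prints the per-approach,
per-habitat diagnostic performance for detecting the highest WHO/ISUP
grade within each tumour.
"""

from hphabitat import RunConfig, run_pipeline
from hphabitat.biopsy import format_report

table, summaries, outdir = run_pipeline(
    RunConfig(seed=1, outdir="habitat_demo_run"), write_png_overlays=False
)
print(format_report(table))

medium = table[(table.approach == "combined") & (table.cluster == "medium")].iloc[0]
print(f"\nmedium combined cluster: PPV {medium.ppv_pct}% "
      f"(tp={medium.tp}, fp={medium.fp}), highest of all rows: "
      f"{bool(medium.ppv == table.ppv.max())}")
print(f"artefacts written to {outdir}/")
# The medium combined [SNR_Pyr + k_PL] cluster — the planted mismatch
# habitat — is the best predictor of the highest intratumoral grade,
# the behaviour the habitat approach is designed to expose.
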