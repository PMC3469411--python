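"""Simulate a complete paired-strain study and recover its truth.

Builds the default error model (a leading-strand mutator with class-level
repair efficiencies, an orientation-biased A->T signature, and one
repair-refractory site at base pair 686), simulates fluctuation assays and
sequenced spectra for proficient/msh2-null pairs in both orientations plus
the ATT0 (interrupted-flank) pair, runs the full pipeline, and compares the
estimated class correction factors with the generator's truth table.
"""

import tempfile

from strandmmr import PipelineConfig, run_pipeline
from strandmmr.simulate import build_error_model, default_design, simulate_study

model = build_error_model()
design = default_design(seed=2012, include_att0=True)
dataset = simulate_study(model, design)

with tempfile.TemporaryDirectory() as study_dir:
    dataset.write(study_dir)
    config = PipelineConfig(
        study_dir=study_dir,
        seed=2012,
        n_resamples=1000,
        censor_at=2000,
        site_positions=(279, 686),
    )
    result = run_pipeline(config)

truth = dataset.truth["expected_class_cfs"]
print(f"{'pair':10s} {'class':18s} {'estimated':>10s} {'truth':>8s}   95% CI")
for pair in result.report["pairs"]:
    att, orientation = pair["att_variant"], pair["orientation"]
    for entry in pair["classes"]:
        true_cf = truth[att].get(entry["selector"], {}).get(orientation)
        if true_cf is None or entry.get("cf") is None:
            continue
        print(
            f"{att}/{orientation:4s} {entry['selector']:18s} "
            f"{entry['cf']:10.1f} {true_cf:8.1f}   "
            f"[{entry['ci_low']:.1f}, {entry['ci_high']:.1f}]"
        )

refractory = next(
    e
    for p in result.report["pairs"]
    if p["att_variant"] == "ATT3" and p["orientation"] == "OR1"
    for e in p["classes"]
    if e["selector"] == "site_686"
)
print(
    f"\nrefractory site 686 (ATT3): CF = {refractory['cf']:.2f}, "
    f"p = {refractory['p_value']:.2f} -> no detectable repair, as designed"
)
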