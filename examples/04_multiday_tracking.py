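"""Track cell identity and silence across a 6-day cohort.

Generates one animal's 6-day cohort with Markov silent/active
dynamics, registers the shifted mean images, links anatomy ROIs
across days, and compares the persistently-silent decay with the
theoretical (1-u)^(k-1) curve.
"""

from pcdrift import PipelineConfig, run_cohort
from pcdrift.synth import BehaviorConfig, CohortConfig, NoiseConfig, gen_cohort

cohort_cfg = CohortConfig(n_cells_per_fov=60, n_days=6, p_silent=0.5,
                          unsilencing_rate=0.54, silencing_rate=0.4,
                          persistent_silent_frac=0.1, seed=6)
sessions, truths = gen_cohort(cohort_cfg, BehaviorConfig(n_laps=10),
                              NoiseConfig(frame_shape=(256, 256)))

summary, tracks = run_cohort(PipelineConfig(seed=7), sessions[0])

print(f"tracked cells (anatomy ROI on every day): {len(tracks)}")
print(f"measured unsilencing rate u = {summary.unsilencing_rate:.3f} "
      f"(generative 0.54)")
print("day   silent%   persistently-silent (norm)   theory (1-u)^(k-1)")
for d, frac in enumerate(summary.per_day_fractions):
    print(f"{d + 1:3d}   {frac['silent_frac']:6.1%}   "
          f"{summary.persistently_silent_normalized[d]:10.3f}   "
          f"{summary.theoretical_curve[d]:10.3f}")
# With a pinned persistently-silent subpopulation the empirical curve
# sits above the theoretical decay from day 2 on: silence is stickier
# than memoryless re-recruitment predicts.
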