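"""Head-movement quantification: RHR and UHD from landmark trajectories.

Builds two synthetic reading sessions over 6 text lines — one reader who
scans straight through, one who re-reads (extra rotations) and fidgets
vertically — and prints the repeated-reading head-rotation ratio (RHR,
rotations per text line) and unconscious head-movement degree (UHD, summed
vertical displacement per line).
"""
from readtask.datatypes import ReadingMeta
from readtask.head import head_features
from readtask.synthetic import LandmarkParams, synth_landmarks

meta = ReadingMeta(n_lines=6)

calm = LandmarkParams(extra_rot_mean=0.0, jitter_sd=0.1, pause_rate=0.0)
restless = LandmarkParams(extra_rot_mean=1.5, jitter_sd=1.0, pause_rate=0.0)

for name, params in [("straight-through", calm), ("re-reading", restless)]:
    lm, truth = synth_landmarks(params, meta, duration_s=12.0, fps=30.0, seed=7)
    feats = head_features(lm, meta)
    print(f"{name:>16}:  RHR = {feats['rhr']:.2f}  (true rotations/line "
          f"{truth['rotations_per_line']:.2f})   UHD = {feats['uhd']:.1f} px/line")

print("\nRHR near 1 means one leftward return per line (no re-reading); "
      "values above 1 count extra re-read sweeps.  Higher UHD means more "
      "vertical head movement per line of text.")
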