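"""Render a synthetic micro-irradiation experiment and run the full analysis.

Builds a small field of nuclei with programmed DNA-damage-response
kinetics, runs segmentation -> tracking -> stripe fitting -> measure of
striation, and compares the recovered MS values against the generator's
ground truth.
"""

import numpy as np

import striation as st

scene = st.SceneConfig(
    field_size_px=(512, 512),
    n_nuclei=12,
    lines_per_field=32,      # 32 laser lines -> 16 px between stripe centers
    width_px=3,
    read_noise_sigma=5.0,
    motion_sigma_px=1.0,
    seed=42,
)
stack, truth = st.render_scene(scene)
print(f"rendered {scene.n_nuclei} nuclei, {stack.n_frames} frames, "
      f"gauge {truth.gauge_px} px, stripe width {truth.width_px} px")

analysis = st.AnalysisConfig(
    mode="live_ddr",
    lines_per_field=scene.lines_per_field,
    width_px=scene.width_px,
    segmentation=st.SegmentationConfig(
        min_area_px=150, max_area_px=5000, smoothing_sigma_px=1.0
    ),
)
result = st.analyze_stack(stack, analysis)
print("run counts:", result.counts)

# How close is the measured MS to the programmed MS_true?
times = list(stack.times_min)
by_id = {t.nucleus_id: t for t in result.tracks}
errors = []
for rec in result.records:
    if rec.flagged:
        continue
    f = times.index(rec.time_min)
    mask = by_id[rec.nucleus_id].mask_at(f)
    ids, counts = np.unique(
        truth.label_images[f][mask.coords[:, 0], mask.coords[:, 1]],
        return_counts=True,
    )
    gt = int(ids[ids > 0][np.argmax(counts[ids > 0])]) - 1
    errors.append(abs(rec.ms - truth.ms_true[f, gt]))
print(f"MS vs ground truth over {len(errors)} records: "
      f"mean |error| = {np.mean(errors):.3f}, max = {np.max(errors):.3f}")
# Mean error of a few hundredths of an MS unit means the pipeline reads the
# programmed recruitment curves essentially noise-limited.
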