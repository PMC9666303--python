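"""Visual receptive fields from image patches.

Generates synthetic 1/f-spectrum images, cuts circular Difference-of-
Gaussians-filtered patches, and trains both BCM variants on the
zero-mean ensemble with the saturating bi-sigmoid transfer function.
Prints the weight-distribution summaries the two rules produce.

Real greyscale images can be substituted via wdbcm.load_images.
"""

import wdbcm as wb

images = wb.generate_synthetic_images(6, 128, seed=42)
pipeline = wb.ImagePipelineConfig(patch_pixels=100, n_patches=1000, rng_seed=3)
patches = wb.make_image_patches(images, pipeline, zero_mean=True)
print(f"trained on {patches.n_patterns} circular patches of "
      f"{patches.n_inputs} pixels each (zero-mean, DoG-filtered)")

for rule in ("standard", "weight_dependent"):
    cfg = wb.PlasticityConfig(
        rule=rule, u=1.0, tau_theta=200, tau_w=2000, rng_seed=2,
        transfer=wb.TransferSpec("bi_sigmoid"),
    )
    traj = wb.simulate(patches, cfg, n_presentations=200_000, record_every=20_000)
    h = wb.weight_histogram(traj.final_state.w)
    print(f"{rule:>17s}: weight std = {h.std:.3f}, skewness = {h.skewness:+.3f}")

print()
print("With zero-mean inputs and a saturating non-linearity both rules form")
print("structured receptive fields; the soft bound of the weight-dependent")
print("rule skews the weight distribution towards positive values, as seen")
print("in cortical synaptic-weight data.")
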