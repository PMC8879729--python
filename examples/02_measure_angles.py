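"""Measure LLA/LSA from a segmented case and compare against truth.

The measurement chain: crop each needed vertebra's binary mask, smooth
(Gaussian, sigma 1), compute the Harris corner response, pick and label
the four endplate corners, pass endplate lines through them, and take
the acute angle between the lines.  The grade follows from the LLA.
"""

from spinemorph import PhantomSpec, generate_phantom, vertebra_corners
from spinemorph.workflow import measure_case

case = generate_phantom(PhantomSpec(seed=0))
report, area = measure_case(case.label_image)

print(f"{'':12}{'measured':>10}{'true':>10}")
print(f"{'LLA (deg)':12}{report.lla_deg:10.2f}{case.true_lla_deg:10.2f}")
print(f"{'LSA (deg)':12}{report.lsa_deg:10.2f}{case.true_lsa_deg:10.2f}")
print(f"{'grade':12}{report.grade:>10}{case.true_grade:>10}")
print(f"region area = {area.area_px:.0f} px^2 (centroid hexagon)")

corners = vertebra_corners(case.label_image, "L1")
print("\nL1 corners (superior-left, superior-right, inferior-left, inferior-right):")
for p, t in zip(corners.points(), case.true_corners["L1"].points()):
    print(f"  detected ({p.x:6.1f}, {p.y:6.1f})   true ({t.x:6.1f}, {t.y:6.1f})")
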