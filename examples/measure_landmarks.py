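"""Measure one egg from manually placed landmarks.

Builds the ten-landmark annotation of a slightly curved, asymmetric egg
(coordinates in pixels, with a 100-px scale bar spanning 0.5 mm), runs the
measurement geometry, and prints the derived traits.
"""

from eggshape import LandmarkSet, Point2D, derive_measurement, measure_from_landmarks

landmarks = LandmarkSet(
    L1=Point2D(20, 200), L2=Point2D(420, 200),          # poles
    M1=Point2D(220, 102), M2=Point2D(220, 304),         # mid (q2) chord
    Q1a=Point2D(120, 105), Q1b=Point2D(120, 295),       # first-quartile chord
    Q3a=Point2D(320, 122), Q3b=Point2D(320, 278),       # third-quartile chord
    S1=Point2D(0, 0), S2=Point2D(100, 0), scale_bar_mm=0.5,
)

raw = measure_from_landmarks(landmarks)
m = derive_measurement(raw, px_per_mm=landmarks.px_per_mm)

print(f"straight length : {raw.straight_length_px:7.1f} px = {m.length_mm:.3f} mm")
print(f"curved length   : {raw.curved_length_px:7.1f} px")
print(f"quartile widths : q1={raw.q1_px:.0f}  q2={raw.q2_px:.0f}  q3={raw.q3_px:.0f} px")
print(f"width           : {m.width_mm:.3f} mm   (widest quartile diameter)")
print(f"volume          : {m.volume_mm3:.4f} mm^3 (rotationally symmetric ellipsoid)")
print(f"aspect ratio    : {m.aspect_ratio:.3f}    (>1: longer than wide)")
print(f"asymmetry       : {m.asymmetry:.3f}    (0 = equal quartile diameters)")
print(f"curvature       : {m.curvature_deg:.2f} deg  (central angle of the length-axis arc)")
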