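"""Design figures of the tapered fiber-optic array, from closed forms.

Computes the single-mode criterion, the per-reflection angle
recursions, the evanescent penetration depth, the hexagonal packing
fraction and resolution gain, and the field-of-view comparison.
"""

import math

import foascope as f

spec = f.TaperedFiberSpec(r=0.6, lambda_=0.55, ncl=1.52, next=1.50)
v = f.v_number(spec)
print(f"V number (r=0.6 um, lambda=550 nm, n=1.52/1.50): {v:.4f}")
print(f"single-mode (V < 2.405): {f.is_single_mode(spec)}")

ray = f.TaperedFiberSpec(n0=1.52, n1=1.50, theta_s=0.3,
                         delta=math.radians(1.0), alpha=math.radians(1.0))
for n in (1, 3, 5):
    print(f"reflection {n}: incidence {math.degrees(f.incident_angle(n, ray)):.2f} deg, "
          f"mode feature angle {math.degrees(f.mode_feature_angle(n, ray)):.2f} deg")
# incidence grows and the feature angle shrinks up the taper, so total
# internal reflection is preserved and mode order drops.

dp = f.penetration_depth(f.TaperedFiberSpec(theta=math.radians(85)))
print(f"evanescent penetration depth at 85 deg: {dp:.3f} um")

print(f"hex packing transmission fraction (d=0.61, D=0.72 um): "
      f"{f.transmission_area_fraction(0.61, 0.72):.3f}")
print(f"hex resolvable period: {f.resolution_period(0.61, 'hexagonal'):.3f} um; "
      f"square: {f.resolution_period(0.61, 'square'):.3f} um; "
      f"gain {f.hex_over_square_gain():.3f}")
print(f"FOV area ratio, FOA (950x700 um) over lens (625x475 um): "
      f"{f.fov_area_ratio((950, 700), (625, 475)):.2f}")
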