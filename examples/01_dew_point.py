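"""Dew point from temperature and relative humidity.

Optical PM sensors over-read when hygroscopic particles swell at high
humidity; dew point is the absolute-moisture proxy used to diagnose that
bias, computed here via the base-10 Magnus vapor-pressure convention.
"""

from pmnet import met

for temp_c, rh_pct in [(20.0, 100.0), (20.0, 50.0), (5.0, 95.0), (12.0, 85.0)]:
    vp = met.vapor_pressure(temp_c, rh_pct)
    dp = met.dew_point(vp)
    print(f"T = {temp_c:5.1f} C, RH = {rh_pct:5.1f}%  ->  VP = {vp:6.2f} hPa, dew point = {dp:5.1f} C")

print()
print("At 100% RH the dew point equals the air temperature; drier air pushes")
print("it lower. Hours with dew point above ~4 C are where the optical")
print("sensors in this kind of network start reading high.")
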