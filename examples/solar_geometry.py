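"""Solar geometry of the five UAV flights over the experimental site.

Computes the solar zenith (SZA) and azimuth (SAA) angle for each flight
time; low zenith means high sun, azimuth is clockwise from north.  The
footprint line shows the ground area one handheld-radiometer reading
covers (28 degree field of view held 1 m above the canopy).
"""

from datetime import datetime, timedelta, timezone

from canopytrait import sensor_footprint, solar_position

SITE = (51.9917, 5.66332)  # degrees N, E
CEST = timezone(timedelta(hours=2))

flights = [
    ("2015-06-05 13:24", datetime(2015, 6, 5, 13, 24, tzinfo=CEST)),
    ("2015-06-24 09:49", datetime(2015, 6, 24, 9, 49, tzinfo=CEST)),
    ("2015-07-07 10:16", datetime(2015, 7, 7, 10, 16, tzinfo=CEST)),
    ("2015-07-16 10:57", datetime(2015, 7, 16, 10, 57, tzinfo=CEST)),
    ("2015-07-31 12:15", datetime(2015, 7, 31, 12, 15, tzinfo=CEST)),
]

print("flight time (UTC+2)   SZA     SAA")
for label, when in flights:
    sza, saa = solar_position(*SITE, when)
    print(f"{label}     {sza:5.1f}   {saa:5.1f}")

diameter, area = sensor_footprint(fov_degrees=28.0, height_m=1.0)
print(f"\nground radiometer footprint: {diameter:.2f} m diameter, {area:.2f} m^2")
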