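"""Convert a local death time to zeitgeber time (hours since sunrise).

A subject dying at 09:30 local in Pittsburgh (UTC-5, daylight saving in
effect) is converted to UTC, the sunrise at the death place is computed
from the NOAA solar equations, and the death is expressed on the ZT scale
[-6, 18) with ZT 0 at sunrise; ZT 0-12 is labelled day, the rest night.
"""

from datetime import datetime

from todrhythm import SubjectRecord
from todrhythm.zeitgeber import (
    SolarQuery,
    day_night_label,
    derive_zt,
    local_death_to_utc,
    sunrise_utc,
)

record = SubjectRecord(
    subject_id="demo", diagnosis="control",
    death_local=datetime(2015, 6, 12, 9, 30),
    tz_offset_hours=-5.0, dst_flag=True,
    latitude=40.44, longitude=-79.99, elevation=300.0,
)

death_utc = local_death_to_utc(record.death_local, record.tz_offset_hours,
                               record.dst_flag)
sunrise = sunrise_utc(SolarQuery(death_utc.date(), record.latitude,
                                 record.longitude, record.elevation))
zt = derive_zt(record)
print(f"death (local): {record.death_local}  ->  UTC: {death_utc}")
print(f"sunrise at death place: {sunrise}")
print(f"zeitgeber time: ZT {zt:.2f}  ({day_night_label(zt)})")
# ZT is the signed hour distance from the previous sunrise: a mid-morning
# June death in Pittsburgh lands around ZT 3-4, inside the day window.
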