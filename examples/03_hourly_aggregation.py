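"""Turn verified detection events into hourly grunt proportions.

Takes a morning of detections from one collar, splits events at clock-hour
boundaries, attaches the observed dominance status, and prints the hourly
record table the behavioural model consumes.
"""

import datetime as dt

from rutvox import peak_rut_date
from rutvox.behaviour import hourly_proportions
from rutvox.detector import DetectionEvent

events = [
    DetectionEvent(120.0, 900.0, 0.96),    # 09:02 - 09:15
    DetectionEvent(3540.0, 3720.0, 0.91),  # 09:59 - 10:02, spans the boundary
    DetectionEvent(7500.0, 8400.0, 0.97),  # 11:05 - 11:20
]
start = dt.datetime(2020, 10, 4, 9, 0, 0)
status_log = [(dt.datetime(2020, 10, 4, 0), dt.datetime(2020, 10, 5, 0), "dominant")]
peak = peak_rut_date([dt.date(2021, 5, 13), dt.date(2021, 5, 15)])
print("estimated peak rut:", peak)

records = hourly_proportions(
    events, start, file_duration_s=4 * 3600, individual="male_5.5",
    status_log=status_log, peak_date=peak,
)
print(records.to_string(index=False))
# proportion is grunt seconds / 3600 per clock hour; the 09:59-10:02 event
# contributes 60 s to hour 9 and 120 s to hour 10.
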