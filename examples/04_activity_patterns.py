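"""Detection-frequency activity patterns from per-recording detections.

Simulates ten days of a 1-min-every-10-min monitoring schedule with a
nocturnal caller and aggregates presence calls into an hourly detection
frequency (positives / recordings per hour, in site-local time).
"""

from datetime import datetime, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from roihmm import detection_frequency, expected_schedule

tz = ZoneInfo("America/Puerto_Rico")
start = datetime(2021, 3, 1, tzinfo=tz)
schedule = expected_schedule(start, start + timedelta(days=10))
print(f"{len(schedule)} scheduled recordings over 10 days "
      f"({len(schedule) // 10} per day)")

rng = np.random.default_rng(2)
rows = []
for i, ts in enumerate(schedule):
    night = ts.hour >= 19 or ts.hour <= 4
    p = 0.5 if night else 0.03
    rows.append({"recording_id": f"r{i}", "timestamp": ts.isoformat(),
                 "species": "tink-frog", "present": int(rng.random() < p)})

series = detection_frequency(pd.DataFrame(rows), grouping="hour",
                             time_zone="America/Puerto_Rico")
print(f"{series.n_detected_total} positive recordings in total")
peak = series.table.loc[series.table["frequency"].idxmax()]
print(f"peak activity at {int(peak['group']):02d}:00 local, "
      f"detection frequency {peak['frequency']:.2f}")
print(series.table.to_string(index=False))
# Night hours sit near 0.5, day hours near 0.03: the planted diel
# pattern, recovered to within binomial noise (60 recordings per hour).
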