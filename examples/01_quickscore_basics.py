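"""Quickscore arithmetic and the legacy single-marker positivity rule.

A pathologist records, per antibody, a staining intensity I (0-3) and the
percent P of tumor cells stained.  The quickscore Q = P*I summarizes both.
"""

from stainclass import Marker, StainRecord, intensity_positive, quickscore

readings = [
    StainRecord(Marker.L858R, 3, 100.0),  # every cell strongly stained
    StainRecord(Marker.L858R, 2, 40.0),   # moderate staining, 40% of cells
    StainRecord(Marker.L858R, 1, 15.0),   # weak but >10% of cells
    StainRecord(Marker.L858R, 3, 10.0),   # strong but exactly 10%
    StainRecord(Marker.L858R, 0, 85.0),   # no staining at all
]

for r in readings:
    print(
        f"I={r.intensity} P={r.percent_positive:5.1f}%  ->  "
        f"Q = {quickscore(r):5.1f}   "
        f"1+/>10% rule: {'positive' if intensity_positive(r) else 'negative'}"
    )

# Q ranges 0-300; the legacy rule calls a section positive only when more
# than 10% of cells stain at intensity 1+ or higher, so the Q=30 reading at
# exactly 10% is negative while the weaker Q=15 reading at 15% is positive.
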