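"""Classify interview responses into detection states and build histories.

A respondent who identifies every look-alike photo and the focal species
without a hint, and reports a within-year sighting inside the focal grid,
yields a certain detection (2); a hint or a misidentified look-alike
downgrades to uncertain (1); a border or stale sighting is a non-detection
(0); failing to identify the focal species voids the replicate.
"""

import numpy as np

import pastocc as po

certain = po.SpeciesResponse(
    species="leopard", paired_set_correct=(True,), hint_used=False,
    focal_identified=True, sighting_reported=True,
    sighting_in_focal_grid=True, sighting_within_past_year=True,
)
hinted = po.SpeciesResponse(
    species="leopard", paired_set_correct=(True,), hint_used=True,
    focal_identified=True, sighting_reported=True,
    sighting_in_focal_grid=True, sighting_within_past_year=True,
)
border = po.SpeciesResponse(
    species="leopard", paired_set_correct=(True,), focal_identified=True,
    sighting_reported=True, sighting_in_focal_grid=False,
    sighting_within_past_year=True,
)
failed = po.SpeciesResponse(
    species="leopard", paired_set_correct=(True,), hint_used=True,
    focal_identified=False,
)

for name, r in [("certain", certain), ("hinted", hinted),
                ("border", border), ("failed ID", failed)]:
    print(f"{name:>10} -> state {po.classify_detection(r)}")

# Two partial-coverage interviews merge into one replicate: the union of
# subgrids, the longer experience, and the higher-certainty outcome.
a = po.InterviewRecord("p1", "G07", frozenset({1, 2}), 12,
                       responses={"leopard": border})
b = po.InterviewRecord("p2", "G07", frozenset({3, 4}), 30,
                       responses={"leopard": certain})
merged = po.merge_paired(a, b)
print(f"\nmerged: subgrids={sorted(merged.subgrids_covered)}, "
      f"experience={merged.years_experience}, state={merged.outcome('leopard')}")

# A detection matrix over three grids; binary layer keeps only state 2.
records = [
    merged,
    po.InterviewRecord("p3", "G08", frozenset({1, 2, 3}), 20,
                       responses={"leopard": hinted}),
    po.InterviewRecord("p4", "G09", frozenset({1, 2, 3, 4}), 8,
                       responses={"leopard": border}),
]
m = po.build_detection_matrix(records, "leopard")
print("\nstates:\n", m.states)
print("binary (certain only):\n", m.binary)
print(f"naive occupancy = {po.naive_occupancy(m):.2f} "
      "(fraction of grids with >=1 certain detection)")
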