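"""Plant GRF motifs on a synthetic Y' terminal fragment and scan them back.

Builds the Y' terminal-restriction-fragment template, synthesizes a sequence
with the Tbf1/Reb1/ACS consensus planted at the annotated features, then
scans both strands with the bundled count matrices at the standard p-value
cutoffs (0.001 for Reb1, 0.005 for Tbf1, 1e-6 for the ACS).
"""

from telochec import build_template, pwm, synthesize_sequence

template = build_template("YpTRF")
sequence = synthesize_sequence(template, seed=3)
matrices = pwm.bundled_matrices()

print(f"{template.name}: {len(sequence)} bp synthetic sequence")
for kind, matrix_id in [("Tbf1_site", "MA0403.1"), ("Reb1_site", "MA0363.1"),
                        ("ACS", "ACS")]:
    planted = [f.start for f in template.features_of(kind)]
    calls = pwm.call_sites(sequence, matrices[matrix_id])
    hits = {c.position for c in calls}
    recovered = sum(p in hits for p in planted)
    print(f"{kind:10s} ({matrix_id}): planted {len(planted)}, "
          f"recovered {recovered}, total calls {len(calls)}")
    for c in calls[:3]:
        print(f"    pos {c.position:5d} strand {c.strand} "
              f"score {c.score:6.2f} bits  p={c.p_value:.2e}")

# Every planted motif scores as an exact consensus window, so it must exceed
# the matrix threshold; extra calls are chance background hits whose rate is
# set by the p-value cutoff per scanned window.
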