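"""Parse a JASPAR-style motif record and scan a promoter for matches.

Builds an information-weighted scoring model from raw counts, then scans a
short promoter on both strands.  Scores are min/max normalised: 1.0 is the
consensus, and the usual reporting threshold is ~0.85-0.95.
"""

from flexsite import PromoterSet, build_pwm, read_jaspar, scan_promoters

JASPAR_TEXT = """>AP1 JUN::FOS
A [  2  1 97  1  1  1 83 ]
C [  1  1  1 48  1 97  6 ]
G [  6 97  1 49  1  1  6 ]
T [ 91  1  1  2 97  1  5 ]
"""

(pfm,) = read_jaspar(JASPAR_TEXT)
pwm = build_pwm(pfm)
print(f"motif {pwm.motif_id}: length {pwm.length} bp, "
      f"information weights {[round(float(c), 2) for c in pwm.ci]}")

# one perfect site (forward), one on the reverse strand, one with a mismatch
promoter = ("ACGGATTACGGCAT" + "TGACTCA" + "ATTCGGACGGATCC"
            + "TGAGTCA"[::-1].translate(str.maketrans("ACGT", "TGCA"))
            + "AGGCATTC" + "TGAATCA" + "GGCCTA")
hits = scan_promoters(pwm, PromoterSet("test", [("promA", promoter)]), 0.80)
for h in hits:
    print(f"  hit at {h.offset:3d} ({h.strand})  score {h.mouse_score:.3f}")
print("A score of 1.000 is a consensus site; the lower-scoring hit carries "
      "one mismatch and would only survive a permissive threshold.")
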