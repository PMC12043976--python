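"""Colorimetric m6A percentage from plate optical densities.

The m6A fraction of an RNA sample is the background-subtracted OD slope per
ng of input RNA, normalized to the positive-control slope.
"""

import io

from epimn.elisa import ElisaMeasurement, m6a_percent, read_plate_csv

well = ElisaMeasurement(
    sample_od=0.8, negative_od=0.2, positive_od=1.4,
    input_rna_ng=200, positive_rna_ng=100,
)
print(f"single well: m6A = {m6a_percent(well):.1f}%")
print("  (0.6 OD over 200 ng vs the positive control's 1.2 OD over 100 ng)")

plate = io.StringIO(
    "sample,sample_od,negative_od,positive_od,input_rna_ng,positive_rna_ng\n"
    "Ctrl,0.70,0.2,1.4,200,100\n"
    "Ctrl,0.90,0.2,1.4,200,100\n"
    "KO,0.45,0.2,1.4,200,100\n"
    "KO,0.55,0.2,1.4,200,100\n"
)
table = read_plate_csv(plate)
print("\nreplicate-averaged plate:")
print(table[["sample", "m6a_percent"]].to_string(index=False))
ctrl, ko = table["m6a_percent"]
print(f"\nKO retains {100 * ko / ctrl:.0f}% of control m6A levels")
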