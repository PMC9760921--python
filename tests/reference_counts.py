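"""Published per-chromosome detection counts for the three-donor human
liver study (Illumina RNA-Seq at FPKM > 0 vs. ONT direct RNA at TPM > 0),
with the proportions as printed in the study's coverage table.

Each row: (chromosome, n_genes, n_illumina, n_ont, n_both,
printed_prop_illumina, printed_prop_ont, printed_prop_union).

The chrY ONT cell prints 0.03 although 12/40 = 0.30 (a known
inconsistency in the printed table); comparisons exclude that one cell.
"""

LIVER_COVERAGE_ROWS = [
    ("1", 2022, 1951, 1361, 1330, 0.96, 0.67, 0.98),
    ("2", 1247, 1210, 895, 881, 0.97, 0.71, 0.98),
    ("3", 1059, 1002, 762, 727, 0.94, 0.71, 0.97),
    ("4", 755, 726, 507, 492, 0.96, 0.67, 0.98),
    ("5", 856, 832, 591, 580, 0.97, 0.69, 0.98),
    ("6", 972, 936, 674, 654, 0.96, 0.69, 0.98),
    ("7", 962, 924, 621, 611, 0.96, 0.64, 0.97),
    ("8", 675, 659, 451, 444, 0.97, 0.66, 0.98),
    ("9", 778, 760, 547, 539, 0.97, 0.70, 0.98),
    ("10", 720, 699, 509, 500, 0.97, 0.70, 0.98),
    ("11", 1281, 1249, 777, 760, 0.97, 0.60, 0.98),
    ("12", 1013, 996, 708, 699, 0.98, 0.69, 0.99),
    ("13", 326, 315, 226, 218, 0.96, 0.69, 0.99),
    ("14", 662, 643, 447, 443, 0.97, 0.67, 0.97),
    ("15", 589, 581, 399, 395, 0.98, 0.67, 0.99),
    ("16", 822, 802, 598, 590, 0.97, 0.72, 0.98),
    ("17", 1126, 1100, 766, 751, 0.97, 0.68, 0.99),
    ("18", 275, 267, 186, 185, 0.97, 0.67, 0.97),
    ("19", 1396, 1342, 949, 932, 0.96, 0.67, 0.97),
    ("20", 537, 508, 355, 344, 0.94, 0.66, 0.96),
    ("21", 209, 201, 137, 132, 0.96, 0.65, 0.98),
    ("22", 459, 442, 317, 309, 0.96, 0.69, 0.98),
    ("X", 812, 729, 453, 430, 0.89, 0.55, 0.92),
    ("Y", 40, 37, 12, 11, 0.92, 0.03, 0.95),
]

TOTAL_GENES = 19593
TOTAL_ILLUMINA = 18911
TOTAL_ONT = 13248
TOTAL_BOTH = 12957
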