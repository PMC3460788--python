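"""Published per-strain summary counts used for arithmetic cross-checks.

These are the printed per-strain tallies from the original 17-strain survey
of mouse vomeronasal receptor coding variation (counts only; all derived
quantities — totals, percentages, ratios, per-codon densities — are
recomputed by this package's functions).  Genome-wide synonymous /
non-synonymous totals and coding-sequence sizes are the companion
whole-genome figures for the same strain panel.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["strain", "group", "vrs_after_parsing", "resolved_kb",
            "unresolved_kb", "all_snps", "nonsyn_snps", "private_snps",
            "truncating_snps"]

_ROWS = [
    ("C57BL/6NJ",   "lab",  203, 316.936, 215.204,    1,    1,    1,  0),
    ("129S1/SvImJ", "lab",  200, 314.377, 217.763,  418,  238,    3,  2),
    ("129S5SvEvBrd","lab",  201, 312.532, 219.608,  396,  224,    1,  2),
    ("129P2/Ola",   "lab",  202, 315.127, 217.013,  416,  231,   24,  4),
    ("A/J",         "lab",  200, 307.621, 224.519,  318,  191,   36,  4),
    ("AKR/J",       "lab",  200, 309.550, 222.590,  311,  170,    7,  4),
    ("BALB/cJ",     "lab",  202, 315.940, 216.200,  301,  184,    1,  4),
    ("C3H/HeJ",     "lab",  202, 314.410, 217.730,  216,  122,    0,  2),
    ("CBA/J",       "lab",  203, 316.936, 215.204,  249,  144,    3,  2),
    ("DBA/2J",      "lab",  201, 311.824, 220.316,  370,  216,   22,  2),
    ("LP/J",        "lab",  202, 314.371, 217.769,  521,  289,   11,  3),
    ("NOD/ShiLtJ",  "lab",  200, 314.167, 217.973,  333,  187,   11,  2),
    ("NZO/HILtJ",   "lab",  199, 313.186, 218.954,  565,  333,   36,  7),
    ("PWK/PhJ",     "wild", 194, 298.987, 233.153, 1409,  789,  508,  6),
    ("CAST/EiJ",    "wild", 183, 280.912, 251.228, 1402,  808,  571,  8),
    ("WSB/EiJ",     "wild", 202, 314.389, 217.751,  462,  291,   84,  4),
    ("SPRET/EiJ",   "wild", 172, 265.669, 266.471, 3519, 1976, 2619, 20),
]


def strain_table() -> pd.DataFrame:
    """Printed per-strain counts, one row per strain."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


# receptor-repertoire-wide figures
VR_CODING_BP_TOTAL = 5_236_930      # total parsed receptor coding sequence
N_REFERENCE_GENES = 366             # receptor genes screened per strain
N_GENE_STRAIN_TOTAL = 6222          # 366 genes x 17 strains
N_GENE_STRAIN_EXCLUDED = 2856       # removed by the parsing cascade
N_GENE_STRAIN_PARSED = 3366

# genome-wide companion counts for the same 17 strains
GENOME_CODING_BP_TOTAL = 599_688_770
GENOME_NONSYN_LAB = 136_968
GENOME_SYN_LAB = 253_181
GENOME_NONSYN_WILD = 178_126
GENOME_SYN_WILD = 361_993
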