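"""Published summary tables for the tomato high-density SNP maps.

Small printed summary statistics of the three interspecific tomato F2 SNP
linkage maps (EXPEN 2000: LA0925 x LA0716, n=79; EXPEN 2012: Moneymaker x
LA0716, n=160; EXPIM 2012: Moneymaker x LA0121, n=183) and the physical
coverage of the SNP array on the SL2.40 tomato assembly.  These printed
totals serve as arithmetic inputs for concordance checks (average bin
intervals, map-length ratios, physical coverage totals); the underlying
per-individual genotypes are not distributed here.
"""

from __future__ import annotations

import pandas as pd

#: SNPs placed on the genotyping array and the number passing manufacturing QC
ARRAY_SNPS_DESIGNED = 8784
ARRAY_SNPS_SCORABLE = 7720

#: per-population totals: markers mapped, genetic bins, coverage (cM), and the
#: mean map length re-estimated from >= 5 cM spaced marker subsets
MAP_TOTALS = pd.DataFrame(
    [
        {"population": "EXPEN2000", "n_individuals": 79, "n_markers": 3503, "n_bins": 1076, "coverage_cM": 1669.9, "resampled_cM": 1252.4},
        {"population": "EXPEN2012", "n_individuals": 160, "n_markers": 3687, "n_bins": 1229, "coverage_cM": 1154.6, "resampled_cM": 1201.2},
        {"population": "EXPIM2012", "n_individuals": 183, "n_markers": 4491, "n_bins": 1358, "coverage_cM": 1049.2, "resampled_cM": 1081.2},
    ]
).set_index("population")

#: physical coverage of the 7,666 physically placed SNPs per chromosome (Mbp)
PHYSICAL_COVERAGE = pd.DataFrame(
    [
        ("ch01", 554, 90.13, 7.36),
        ("ch02", 871, 49.48, 3.83),
        ("ch03", 679, 64.70, 4.38),
        ("ch04", 861, 64.01, 2.03),
        ("ch05", 783, 64.91, 2.70),
        ("ch06", 748, 45.88, 2.66),
        ("ch07", 443, 64.98, 3.93),
        ("ch08", 396, 62.97, 2.95),
        ("ch09", 473, 67.60, 4.52),
        ("ch10", 405, 64.74, 3.17),
        ("ch11", 1059, 53.28, 2.37),
        ("ch12", 394, 65.32, 4.73),
    ],
    columns=["chromosome", "n_markers", "coverage_Mbp", "max_gap_Mbp"],
).set_index("chromosome")


def pass_rate_percent(passed: int, total: int) -> float:
    """Share of designed assays that are scorable, in percent."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * passed / total
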