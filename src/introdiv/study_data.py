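"""Published per-locus summary tables for the *Lutzomyia longipalpis* complex.

A multilocus survey of 21 nuclear loci in four Brazilian populations — two
sympatric sibling species from Sobral (1S and 2S) and two allopatric siblings
from Lapinha and Pancas — reported per-locus alignment lengths, sample sizes,
pairwise FST with shared/fixed site counts, and IM model parameter estimates.
These printed values serve two roles here: they drive the comparison layer
directly (panel bypass, no sequences needed) and they parameterize the
synthetic-study generator so simulated data matches the study's scale.
"""

from __future__ import annotations

from .compare import FstPanel
from .im import IMParams

POPULATIONS = ("sobral1s", "sobral2s", "lapinha", "pancas")
SYMPATRIC_PAIR = ("sobral1s", "sobral2s")
ALLOPATRIC_PAIR = ("lapinha", "pancas")

LOCI = (
    "CG9297", "CG9769", "eno", "kinC", "mlcc", "norpA", "obp19a",
    "rpL17A", "rpL36", "rpS19", "sesB", "slh", "sec22", "sod2",
    "tfIIAL", "tropC", "up", "zcop", "cac", "para", "per",
)

# aligned length in bp per locus
LENGTHS_BP = {
    "CG9297": 474, "CG9769": 378, "eno": 245, "kinC": 664, "mlcc": 217,
    "norpA": 104, "obp19a": 164, "rpL17A": 302, "rpL36": 450, "rpS19": 300,
    "sesB": 89, "slh": 258, "sec22": 429, "sod2": 310, "tfIIAL": 377,
    "tropC": 483, "up": 404, "zcop": 386, "cac": 109, "para": 377, "per": 266,
}

# sequences sampled per population per locus (order: sobral1s, sobral2s, lapinha, pancas)
SAMPLE_SIZES = {
    "CG9297": (32, 29, 18, 25), "CG9769": (24, 24, 20, 14), "eno": (28, 32, 29, 30),
    "kinC": (17, 23, 24, 24), "mlcc": (30, 28, 17, 24), "norpA": (32, 30, 38, 25),
    "obp19a": (32, 31, 28, 26), "rpL17A": (31, 31, 25, 14), "rpL36": (21, 16, 32, 23),
    "rpS19": (33, 40, 27, 10), "sesB": (23, 26, 21, 15), "slh": (27, 30, 19, 16),
    "sec22": (17, 15, 29, 16), "sod2": (26, 27, 27, 16), "tfIIAL": (14, 18, 20, 38),
    "tropC": (27, 27, 29, 31), "up": (21, 22, 14, 16), "zcop": (30, 16, 28, 21),
    "cac": (23, 22, 20, 26), "para": (27, 22, 21, 29), "per": (24, 23, 23, 19),
}

# per-locus pairwise FST and shared (Ss) / fixed (Sf) site counts
FST_SYMPATRIC = {
    "CG9297": 0.106, "CG9769": 0.059, "eno": 0.007, "kinC": 0.145, "mlcc": 0.021,
    "norpA": 0.000, "obp19a": 0.032, "rpL17A": 0.115, "rpL36": 0.034,
    "rpS19": 0.351, "sesB": 0.334, "slh": 0.184, "sec22": 0.475, "sod2": 0.276,
    "tfIIAL": 0.165, "tropC": 0.359, "up": 0.547, "zcop": 0.036, "cac": 0.076,
    "para": 0.766, "per": 0.395,
}
FST_ALLOPATRIC = {
    "CG9297": 0.486, "CG9769": 0.954, "eno": 0.134, "kinC": 0.331, "mlcc": 0.250,
    "norpA": 0.130, "obp19a": 0.138, "rpL17A": 0.782, "rpL36": 0.300,
    "rpS19": 0.486, "sesB": 0.796, "slh": 0.568, "sec22": 0.461, "sod2": 0.337,
    "tfIIAL": 0.350, "tropC": 0.705, "up": 0.438, "zcop": 0.454, "cac": 0.130,
    "para": 0.815, "per": 0.471,
}
SS_SYMPATRIC = {
    "CG9297": 26, "CG9769": 3, "eno": 2, "kinC": 10, "mlcc": 3, "norpA": 6,
    "obp19a": 14, "rpL17A": 11, "rpL36": 29, "rpS19": 10, "sesB": 0, "slh": 13,
    "sec22": 3, "sod2": 7, "tfIIAL": 15, "tropC": 5, "up": 5, "zcop": 5,
    "cac": 4, "para": 1, "per": 6,
}
SF_SYMPATRIC = {name: 0 for name in LOCI} | {"para": 3}
SS_ALLOPATRIC = {
    "CG9297": 9, "CG9769": 0, "eno": 0, "kinC": 10, "mlcc": 0, "norpA": 3,
    "obp19a": 8, "rpL17A": 0, "rpL36": 9, "rpS19": 3, "sesB": 0, "slh": 0,
    "sec22": 1, "sod2": 0, "tfIIAL": 20, "tropC": 0, "up": 0, "zcop": 0,
    "cac": 4, "para": 0, "per": 3,
}
SF_ALLOPATRIC = {name: 0 for name in LOCI} | {
    "CG9769": 8, "rpL17A": 2, "sec22": 1, "tropC": 1, "up": 1, "para": 4,
}

# IM model point estimates (mutational units) for the two comparisons.
# Directions: sympatric population 1 = sobral1s, 2 = sobral2s;
# allopatric population 1 = lapinha, 2 = pancas.
IM_SYMPATRIC = IMParams(
    theta1=2.9127, theta2=2.056, thetaA=0.8661, t=0.9463, m1=0.1375, m2=1.425
)
IM_ALLOPATRIC = IMParams(
    theta1=1.4134, theta2=1.4355, thetaA=1.4901, t=0.8863, m1=0.0625, m2=0.2125
)

# mutation-rate constants for unit conversion
SYN_RATE_PER_SITE_YEAR = 1.56e-8
NONSYN_RATE_PER_SITE_YEAR = 1.91e-9
MU_GM_PER_LOCUS_YEAR = 1.77e-6
GENERATIONS_PER_YEAR = 10.0

# envelope of the printed per-locus polymorphism summaries
PI_ENVELOPE = (0.0, 0.05)
S_ENVELOPE = (0, 60)


def fst_panel() -> FstPanel:
    """The published 21-locus FST panel as a :class:`FstPanel`."""
    import numpy as np

    return FstPanel(
        loci=LOCI,
        fst_symp=np.array([FST_SYMPATRIC[x] for x in LOCI]),
        fst_allo=np.array([FST_ALLOPATRIC[x] for x in LOCI]),
    )


def total_fixed_differences(pair: str = "allopatric") -> int:
    table = SF_ALLOPATRIC if pair == "allopatric" else SF_SYMPATRIC
    return sum(table.values())
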