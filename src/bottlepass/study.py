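"""Named default configurations and reported values from the squid-Vibrio study.

Everything here is an explicit, overridable input: the passage scheme of the
host-selection experiment, the binK mutation-supply parameter table, the two
bottleneck regimes used for the survival approximation, and the selection
coefficients the competition assays reported. Nothing in the library hard-codes
these numbers.
"""

from __future__ import annotations

from .simulate import PassageScheme
from .supply import MutationSupplyParams
from .survival import RECRUITMENT, VENTING, BottleneckRegime

__all__ = [
    "STUDY_SCHEME",
    "BINK_SUPPLY",
    "RECRUITMENT",
    "VENTING",
    "REPORTED_SELECTION_24H",
    "REPORTED_SELECTION_48H",
    "REPORTED_SELECTION_MAX",
    "DETECTION_FLOOR_CFU",
    "N_PARALLEL_SQUID",
]

#: Serial-passage scheme of the evolution experiment: 5-cell inoculum grown to
#: 2.4e8, 12-cell recruitment, 5e5-cell organ capacity, 95% venting, four
#: daily cycles per host, 15 hosts.
STUDY_SCHEME = PassageScheme()

#: binK mutation-supply parameters: genome mutation rate 2.08e-8 per bp per
#: division, 2,595 bp locus with ~2/3 of positions non-synonymous, inoculum
#: expansion from 5 to 2.4e8 cells.
BINK_SUPPLY = MutationSupplyParams(
    mu=2.08e-8,
    locus_length_bp=2595,
    nonsyn_fraction=2.0 / 3.0,
    n0=5,
    n_final=2.4e8,
)

#: Selection coefficients (estimator scale) reported for the binK1 variant in
#: co-colonized squid at 24 and 48 hr, and the largest single-host estimate.
REPORTED_SELECTION_24H = 1.1
REPORTED_SELECTION_48H = 1.8
REPORTED_SELECTION_MAX = 5.3

#: Minimum abundance recoverable by dilution plating of a light-organ homogenate.
DETECTION_FLOOR_CFU = 15.0

#: Parallel squid lineages founded per ancestral population.
N_PARALLEL_SQUID = 10
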