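"""Published summary constants of the Orís landfill griffon vulture
ringing programme (2012-2022) and the arithmetic checks built on them.

The raw ringing data are not publicly deposited; these printed totals are
the self-contained quantities the study reports: the organic-matter
tonnage dumped at the landfill before and after the waste treatment
centre opened, and the first-capture and never-recaptured counts per age
class. They calibrate the ``paper_like`` simulation preset and anchor the
package's arithmetic acceptance checks.
"""

from __future__ import annotations

# Annual organic matter dumped in the landfill (metric tons)
ORGANIC_TONNES_2012 = 17_942
ORGANIC_TONNES_2022 = 450
ORGANIC_TONNES_BEFORE_WTC = 14_389     # before the waste treatment centre
ORGANIC_TONNES_FINAL_PERIOD = 514      # mean of the final four study years

# First captures by age class, 2012-2022
FIRST_CAPTURES = {"juvenile": 637, "immature": 1104, "adult": 1673}
# ... of which never recaptured
NEVER_RECAPTURED = {"juvenile": 424, "immature": 800, "adult": 1274}


def percent_reduction(before: float, after: float) -> float:
    """Percentage reduction from ``before`` to ``after``."""
    if before <= 0:
        raise ValueError("the reference quantity must be positive")
    return 100.0 * (1.0 - after / before)


def never_recaptured_percent(age_class: str) -> float:
    """Share of an age class's first captures that were never seen again."""
    return 100.0 * NEVER_RECAPTURED[age_class] / FIRST_CAPTURES[age_class]


def total_marked() -> int:
    """Total marked individuals across the three age classes."""
    return sum(FIRST_CAPTURES.values())
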