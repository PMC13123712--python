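"""Demographic summary tables of the pediatric circumcision cohort.

These published group-level counts (enrollment by indication, the
pre/post follow-up subgroup, and the ethnicity breakdown of the
elective vs pathological-phimosis comparison) are the inputs for the
package's worked demographic examples. Individual-level data are not
included.
"""

from __future__ import annotations

import pandas as pd

ETHNICITIES = ("caucasian", "middle_eastern", "asian", "african_american", "other")

#: Indication for circumcision among the 75 enrolled participants.
ENROLLMENT_BY_INDICATION = pd.Series(
    {"elective": 23, "non_elective": 20, "pathological_phimosis": 32},
    name="participants",
)

#: Indication among the 51 participants with pre- and post-circumcision data.
FOLLOWUP_BY_INDICATION = pd.Series(
    {"elective": 12, "non_elective": 13, "pathological_phimosis": 26},
    name="participants",
)

#: Ethnicity by group for the elective vs pathological-phimosis comparison
#: (rows: group; columns: ethnoracial identity).
PHIMOSIS_ETHNICITY = pd.DataFrame(
    [[11, 7, 3, 1, 1], [27, 1, 2, 1, 1]],
    index=pd.Index(["elective", "pathological_phimosis"], name="group"),
    columns=list(ETHNICITIES),
)
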