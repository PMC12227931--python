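"""Case-finding algorithms are declarative multi-source rules.

Shows the exclusion mechanism: a subject with qualifying Hashimoto-
thyroiditis events is vetoed when a thyrotoxic-drug prescription falls in
the 12 months before their first qualifying event (a drug-induced
thyroiditis look-alike), while the same prescription further in the past
leaves the flag intact.
"""

from datetime import date

import pandas as pd

from mscomorb import CaseAlgorithm, apply_algorithm

algorithm = CaseAlgorithm(
    disease="hashimoto_thyroiditis",
    stream_codes={"copay_exemption": frozenset({"EXEM:ht"})},
    window=(date(2013, 1, 1), date(2017, 12, 31)),
    exclusion_codes=frozenset({"DRUG:thyrotoxic"}),
    exclusion_months=12,
)

events = pd.DataFrame(
    [
        ("drug_induced", "copay_exemption", "2015-06-01", "EXEM:ht"),
        ("drug_induced", "drug_prescription", "2014-09-01", "DRUG:thyrotoxic"),
        ("genuine_case", "copay_exemption", "2015-06-01", "EXEM:ht"),
        ("genuine_case", "drug_prescription", "2013-02-01", "DRUG:thyrotoxic"),
    ],
    columns=["subject_id", "stream", "date", "code"],
)

flagged = apply_algorithm(events, algorithm)
print(f"flagged subjects: {sorted(flagged)}")
# Only 'genuine_case' is flagged: the exclusion window is anchored at the
# first qualifying event and looks back 12 months.
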