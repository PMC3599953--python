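"""Derive a self-reported proxy 'diagnosis year' from survey answers.

The baseline survey records current age in years and months and, for women
reporting a breast-cancer diagnosis, their whole-years age at diagnosis.
The proxy window is the 12 calendar months during which the respondent was
that age.
"""

import datetime as dt

from caseflag import compute_proxy_diagnosis_window

completion = dt.date(2008, 8, 19)
window = compute_proxy_diagnosis_window(
    completion, age_years=72, age_months=4,
    reported_breast_cancer=True, reported_age_at_diagnosis=68)

print(f"recruited {completion}, aged 72y 4m, diagnosis reported at age 68")
print(f"proxy diagnosis year: {window}")
print("-> the registry is searched for a diagnosis inside this 12-month window;")
print("   overlap with Jul 2004-Dec 2005 decides whether the report is evaluable.")
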