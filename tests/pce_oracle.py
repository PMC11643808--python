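"""Independent pooled-cohort-equation oracle.

Each race-sex group is written out as one explicit arithmetic expression,
transcribed separately from the published 2013 coefficient tables, so it
shares no code or data structure with the package implementation.
"""

import math


def white_male(age, tc, hdl, sbp, treated, smoker, diabetic):
    la, ltc, lh, ls = math.log(age), math.log(tc), math.log(hdl), math.log(sbp)
    s = (12.344 * la + 11.853 * ltc - 2.664 * la * ltc - 7.990 * lh + 1.769 * la * lh
         + (1.797 if treated else 1.764) * ls
         + (7.837 - 1.795 * la) * (1.0 if smoker else 0.0)
         + (0.658 if diabetic else 0.0))
    return 1.0 - 0.9144 ** math.exp(s - 61.18)


def white_female(age, tc, hdl, sbp, treated, smoker, diabetic):
    la, ltc, lh, ls = math.log(age), math.log(tc), math.log(hdl), math.log(sbp)
    s = (-29.799 * la + 4.884 * la ** 2 + 13.540 * ltc - 3.114 * la * ltc
         - 13.578 * lh + 3.149 * la * lh
         + (2.019 if treated else 1.957) * ls
         + (7.574 - 1.665 * la) * (1.0 if smoker else 0.0)
         + (0.661 if diabetic else 0.0))
    return 1.0 - 0.9665 ** math.exp(s + 29.18)


def black_male(age, tc, hdl, sbp, treated, smoker, diabetic):
    la, ltc, lh, ls = math.log(age), math.log(tc), math.log(hdl), math.log(sbp)
    s = (2.469 * la + 0.302 * ltc - 0.307 * lh
         + (1.916 if treated else 1.809) * ls
         + (0.549 if smoker else 0.0) + (0.645 if diabetic else 0.0))
    return 1.0 - 0.8954 ** math.exp(s - 19.54)


def black_female(age, tc, hdl, sbp, treated, smoker, diabetic):
    la, ltc, lh, ls = math.log(age), math.log(tc), math.log(hdl), math.log(sbp)
    if treated:
        bp_part = 29.291 * ls - 6.432 * la * ls
    else:
        bp_part = 27.820 * ls - 6.087 * la * ls
    s = (17.114 * la + 0.940 * ltc - 18.920 * lh + 4.475 * la * lh + bp_part
         + (0.691 if smoker else 0.0) + (0.874 if diabetic else 0.0))
    return 1.0 - 0.9533 ** math.exp(s - 86.61)


def oracle_risk(age, sex, race, tc, hdl, sbp, treated, smoker, diabetic):
    fn = {("male", "african_american"): black_male,
          ("female", "african_american"): black_female,
          ("male", "white_other"): white_male,
          ("female", "white_other"): white_female}[(sex, race)]
    return fn(age, tc, hdl, sbp, treated, smoker, diabetic)
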