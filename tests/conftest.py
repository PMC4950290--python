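import numpy as np
import pytest

import cytoclass as cc


@pytest.fixture(scope="session")
def cohort():
    """Calibrated synthetic two-cohort-sized table (n=1642, fixed seed)."""
    return cc.generate_cohort(cc.default_config(n_subjects=1642, seed=11))


@pytest.fixture(scope="session")
def responders(cohort):
    qr = cc.qc_filter(cohort)
    return cc.net_responses(cohort, subject_ids=qr.included)


@pytest.fixture(scope="session")
def tertile_codes(responders):
    scheme = cc.fit_discretizer(responders, "tertile")
    codes, class0 = cc.apply_discretizer(scheme, responders)
    return scheme, codes, class0


def brute_force_ari(a, b):
    """Independent pair-enumeration oracle for the adjusted Rand index.

    Counts agreeing/disagreeing item pairs directly and applies the
    chance correction from the raw pair counts.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    together_a = together_b = together_both = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            together_a += sa
            together_b += sb
            together_both += sa and sb
            n_pairs += 1
    expected = together_a * together_b / n_pairs
    max_index = 0.5 * (together_a + together_b)
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)
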