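"""Shared fixtures: synthetic plates and their preprocessed/fitted forms.

Everything is generated programmatically from the seeded scenario fixtures, so
the suite needs no data files.  Expensive fits are session-scoped.
"""

from collections import defaultdict

import pytest

from ktau import PlateauAssociation, generate_arrestin_plate
from ktau.qc import preprocess
from ktau.simulate import builtin_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return builtin_fixtures()


@pytest.fixture(scope="session")
def angii_sat_tcs(fixtures):
    """Preprocessed saturating-concentration AngII-like replicates (n=3)."""
    traces = generate_arrestin_plate(fixtures["angii-arrestin-saturating"])
    return [preprocess(tr) for tr in traces]


@pytest.fixture(scope="session")
def angii_sat_fit(angii_sat_tcs):
    return PlateauAssociation(angii_sat_tcs).fit()


@pytest.fixture(scope="session")
def angii_dose_response_fits(fixtures):
    """Association fits per concentration for the AngII-like dose-response."""
    traces = generate_arrestin_plate(fixtures["angii-arrestin"])
    groups = defaultdict(list)
    for tr in traces:
        groups[tr.conc].append(preprocess(tr))
    return [PlateauAssociation(tcs).fit() for _, tcs in sorted(groups.items())]


@pytest.fixture(scope="session")
def angii_dose_response_tcs(fixtures):
    traces = generate_arrestin_plate(fixtures["angii-arrestin"])
    return [preprocess(tr) for tr in traces]
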