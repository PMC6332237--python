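"""Shared fixtures for the haloscreen test suite."""

from __future__ import annotations

import pytest

from haloscreen.formula import parse_formula


# Reported [M+H]+ accurate masses and compositions for the eight
# rugulovasine-series compounds (positive-ESI, high resolution).
# Frozen here independently of the package's library module so the
# tests cross-check the embedded reference data rather than echo it.
REPORTED_PRECURSORS = [
    ("rugulovasine A", 269.1284, "C16H17O2N2"),
    ("rugulovasine B", 269.1284, "C16H17O2N2"),
    ("8-chlororugulovasine A", 303.0894, "C16H16O2N2Cl"),
    ("8-chlororugulovasine B", 303.0894, "C16H16O2N2Cl"),
    ("2,8-dichlororugulovasine A", 337.0503, "C16H15O2N2Cl2"),
    ("2,8-dichlororugulovasine B", 337.0501, "C16H15O2N2Cl2"),
    ("2-bromorugulovasine A", 347.0388, "C16H16O2N2Br"),
    ("2-bromorugulovasine B", 347.0387, "C16H16O2N2Br"),
]


@pytest.fixture(scope="session")
def rugulovasine_ion():
    return parse_formula("C16H17O2N2", 1)


@pytest.fixture(scope="session")
def dichloro_ion():
    return parse_formula("C16H15O2N2Cl2", 1)
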