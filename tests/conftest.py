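"""Shared fixtures: small synthetic reaction sets, reused across modules."""

from __future__ import annotations

import pytest

import atommap as am


@pytest.fixture(scope="session")
def examples():
    """60 synthetic mapped reactions over all 8 reaction classes."""
    return am.generate(n=60, seed=7)


@pytest.fixture(scope="session")
def examples_by_class(examples):
    by_class: dict[str, list] = {}
    for record, gold, name in examples:
        by_class.setdefault(name, []).append((record, gold))
    return by_class


@pytest.fixture(scope="session")
def ester_example(examples_by_class):
    return examples_by_class["ester_hydrolysis"][0]


@pytest.fixture(scope="session")
def sn2_record():
    return am.parse_reaction("[CH3:1][Br:2].[I-:3]>>[CH3:1][I:3]", "sn2-toy")
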