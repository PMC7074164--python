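"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from itertools import product as _cartesian

import numpy as np
import pytest

from ahlscreen.formula import Formula, element_table
from ahlscreen.library import default_standards, generate_candidate_space


@pytest.fixture(scope="session")
def grid():
    return generate_candidate_space()

@pytest.fixture(scope="session")
def standards():
    return default_standards()


def enumerate_pattern(f: Formula) -> dict:
    """Brute-force isotope envelope by exhaustive isotopologue enumeration.

    Independent of the convolution implementation: expands the exact
    multinomial distribution of isotope-count vectors per element and sums
    probabilities by total nominal mass offset.  Only feasible for small
    formulas; returns offset -> intensity relative to offset 0.
    """
    per_element = []
    for sym, n in f.counts.items():
        isotopes = element_table()[sym].isotopes
        base_mass = isotopes[0][0]
        vectors = []

        def gen(remaining, idx, current):
            if idx == len(isotopes) - 1:
                vectors.append(current + [remaining])
                return
            for k in range(remaining + 1):
                gen(remaining - k, idx + 1, current + [k])

        gen(n, 0, [])
        options = []
        for vec in vectors:
            prob = float(math.factorial(n))
            for k in vec:
                prob /= math.factorial(k)
            offset = 0
            for k, (mass, abundance) in zip(vec, isotopes):
                prob *= abundance ** k
                offset += k * int(round(mass - base_mass))
            options.append((offset, prob))
        per_element.append(options)

    total: dict = {}
    for combo in _cartesian(*per_element):
        off = sum(c[0] for c in combo)
        p = math.prod(c[1] for c in combo)
        total[off] = total.get(off, 0.0) + p
    base = total[0]
    return {k: v / base for k, v in sorted(total.items())}
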