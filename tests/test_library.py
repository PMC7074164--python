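"""AHL congener space: naming, formulas, fragments, candidate grid, standards."""

import pytest

from ahlscreen.formula import MassConvention, ion_mz, monoisotopic_mass, ppm_error
from ahlscreen.library import (
    AHLSpec,
    STANDARD_NAMES,
    acyl_fragment_mz,
    fragment_formulas,
    generate_candidate_space,
    ion_formula,
    lactone_fragment_mz,
    neutral_formula,
    precursor_mz,
)


@pytest.mark.parametrize(
    "name, n, u, subst",
    [
        ("C6-AHL", 6, 0, "plain"),
        ("OC19-AHL", 19, 0, "3-oxo"),
        ("OHC14:1-AHL", 14, 1, "3-hydroxy"),
        ("C10:1-AHL", 10, 1, "plain"),
    ],
)
def test_name_grammar(name, n, u, subst):
    s = AHLSpec.from_name(name)
    assert (s.n, s.u, s.subst) == (n, u, subst)
    assert s.name == name


@pytest.mark.parametrize("bad", ["C3-AHL", "HC6-AHL", "C6:2-AHL", "C6", "OHC-AHL"])
def test_name_grammar_rejects(bad):
    with pytest.raises(ValueError):
        AHLSpec.from_name(bad)


def test_spec_validation():
    with pytest.raises(ValueError):
        AHLSpec(3)
    with pytest.raises(ValueError):
        AHLSpec(6, u=2)
    with pytest.raises(ValueError):
        AHLSpec(6, subst="4-oxo")


def test_naming_roundtrip_whole_grid(grid):
    for cand in grid:
        assert AHLSpec.from_name(cand.spec.name) == cand.spec


@pytest.mark.parametrize(
    "spec, neutral, ion",
    [
        # the long-chain inference chain: plain and 3-oxo C19
        (AHLSpec(19, 0, "3-oxo"), "C23H41NO4", "C23H42NO4"),
        (AHLSpec(19, 0, "plain"), "C23H43NO3", "C23H44NO3"),
        (AHLSpec(6, 0, "plain"), "C10H17NO3", "C10H18NO3"),
    ],
)
def test_neutral_and_ion_formulas(spec, neutral, ion):
    assert neutral_formula(spec).hill() == neutral
    assert ion_formula(spec).hill() == ion


@pytest.mark.parametrize(
    "spec, printed",
    [
        (AHLSpec(19, 0, "plain"), 382.3312),
        (AHLSpec(19, 0, "3-oxo"), 396.3104),
        (AHLSpec(6, 0, "plain"), 200.1280),
    ],
)
def test_precursor_mz_within_3ppm_of_printed(spec, printed):
    assert abs(ppm_error(printed, precursor_mz(spec))) < 3.0


def test_precursor_mz_4dp():
    assert precursor_mz(AHLSpec(19, 0, "plain")) == pytest.approx(382.3316, abs=5e-5)
    assert precursor_mz(AHLSpec(6, 0, "plain")) == pytest.approx(200.1281, abs=5e-5)


def test_unsaturation_mass_gap():
    for subst in ("plain", "3-oxo", "3-hydroxy"):
        gap = precursor_mz(AHLSpec(18, 0, subst)) - precursor_mz(AHLSpec(18, 1, subst))
        assert gap == pytest.approx(2.0157, abs=5e-5)


@pytest.mark.parametrize(
    "spec, acyl",
    [
        (AHLSpec(19, 0, "plain"), "C19H37O"),
        (AHLSpec(19, 0, "3-oxo"), "C19H35O2"),
        (AHLSpec(8, 1, "3-hydroxy"), "C8H13O2"),
    ],
)
def test_acyl_fragment_formulas(spec, acyl):
    assert fragment_formulas(spec)["acyl"].hill() == acyl


def test_diagnostic_fragment_is_universal(grid):
    assert lactone_fragment_mz() == pytest.approx(102.0550, abs=5e-5)
    for cand in grid[:10]:
        assert fragment_formulas(cand.spec)["lactone"].hill() == "C4H8NO2"


def test_fragment_mass_closure(grid):
    # both diagnostic fragments are cations, each paired with a neutral loss:
    # lactone+ + acylium+ carries one proton more than the [M+H]+ ion
    from ahlscreen.formula import Formula

    proton = Formula({"H": 1})
    for cand in grid:
        frags = fragment_formulas(cand.spec)
        assert frags["lactone"] + frags["acyl"] == ion_formula(cand.spec) + proton


def test_grid_cardinality_and_order(grid):
    assert len(grid) == 17 * 3 * 2
    mzs = [c.mz for c in grid]
    assert mzs == sorted(mzs)
    single = generate_candidate_space(6, 6, allow_unsat=False, substitutions=("plain",))
    assert len(single) == 1
    assert single[0].mz == pytest.approx(200.1281, abs=5e-5)
    with pytest.raises(ValueError):
        generate_candidate_space(3, 10)


def test_isomer_groups_link_oxo_and_unsat_hydroxy(grid):
    by_spec = {c.spec: c for c in grid}
    for n in range(6, 20):
        oc = by_spec[AHLSpec(n, 0, "3-oxo")]
        ohc1 = by_spec[AHLSpec(n, 1, "3-hydroxy")]
        assert ion_formula(oc.spec) == ion_formula(ohc1.spec)
        assert oc.isomer_group == ohc1.isomer_group
        assert oc.mz == ohc1.mz


def test_precursor_mz_monotone_in_chain_length():
    for subst in ("plain", "3-oxo", "3-hydroxy"):
        for u in (0, 1):
            mzs = [precursor_mz(AHLSpec(n, u, subst)) for n in range(4, 21)]
            assert all(b > a for a, b in zip(mzs, mzs[1:]))


def test_congener_census_union_vs_reported():
    from ahlscreen.study_tables import REPORTED_CENSUS, congener_census

    census = congener_census()
    assert census["saturated"] + census["unsaturated"] == 24
    assert census["unsaturated"] == 5
    # the summary census of the source disagrees with its own tables
    assert census != REPORTED_CENSUS


def test_default_standards_table(standards):
    names = [e.spec.name for e in standards]
    assert names == list(STANDARD_NAMES)
    assert len(names) == 21
    assert all(e.reference_rt_min > 0 for e in standards)
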