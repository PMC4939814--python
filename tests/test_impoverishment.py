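"""Gross vs net poverty measures and the impoverishment effect of OOP."""

import numpy as np
import pytest

from finprot.errors import InputError
from finprot.impoverishment import (
    POVERTY_LINE_PRESETS,
    PovertyLine,
    impoverished_population,
    impoverishment_effect,
    poverty_gap,
    poverty_head_count,
    poverty_measures,
)

from conftest import expand_to_persons, make_dataset, random_dataset

PL100 = PovertyLine(100.0, "toy")


@pytest.fixture
def toy_poverty():
    # per-capita (y, s): (90, 2), (150, 1), (80, 3); no OOP
    return make_dataset(
        total=[180.0, 150.0, 240.0],
        food=[50.0, 50.0, 50.0],
        oop=[0.0, 0.0, 0.0],
        size=[2, 1, 3],
    )


def test_head_count_person_weighted_enumeration(toy_poverty):
    # 2 + 3 of 6 people are below 100
    assert poverty_head_count(toy_poverty, PL100) == pytest.approx(5 / 6)


def test_head_count_zero_when_line_below_everyone(toy_poverty):
    assert poverty_head_count(toy_poverty, PovertyLine(10.0)) == 0.0


def test_head_count_strict_inequality_at_line():
    ds = make_dataset([100.0], [10.0], [0.0], size=[1])
    assert poverty_head_count(ds, PL100) == 0.0  # exactly at PL -> not poor


def test_gap_manual_arithmetic(toy_poverty):
    gap, ng, nmpg = poverty_gap(toy_poverty, PL100)
    assert gap == pytest.approx((2 * 10 + 3 * 20) / 6)  # 13.333
    assert ng == pytest.approx(gap / 100.0)
    assert nmpg == pytest.approx(ng / (5 / 6))


def test_gap_zero_and_nmpg_undefined_when_nobody_poor(toy_poverty):
    gap, ng, nmpg = poverty_gap(toy_poverty, PovertyLine(10.0))
    assert gap == 0.0 and ng == 0.0 and nmpg is None


def test_printed_normalized_gap_relation():
    # the normalized gap is the gap divided by the line: 6953.57 MNT against
    # a 118,668 MNT line is 5.86 %
    assert round(100 * 6953.57 / POVERTY_LINE_PRESETS["mongolia_national_2012"].value, 2) == 5.86


def test_net_basis_single_household_crossing():
    # y = 110, per-capita OOP 20: gross non-poor, net poor
    ds = make_dataset([110.0], [10.0], [20.0], size=[1])
    eff = impoverishment_effect(ds, PL100)
    assert eff.gross.head_count == 0.0
    assert eff.net.head_count == 1.0
    assert eff.absolute_change["head_count"] == pytest.approx(1.0)
    assert eff.relative_change["head_count"] is None  # gross is zero


def test_no_oop_means_no_change(rng):
    ds = random_dataset(rng, 60, zero_oop_prob=1.0)
    line = PovertyLine(float(np.median(ds.total_expenditure / ds.size)))
    eff = impoverishment_effect(ds, line)
    for m, v in eff.absolute_change.items():
        assert v == pytest.approx(0.0)


def test_net_dominates_gross(rng):
    for _ in range(5):
        ds = random_dataset(rng, 150)
        line = PovertyLine(float(np.quantile(ds.total_expenditure / ds.size, 0.35)))
        eff = impoverishment_effect(ds, line)
        assert eff.net.head_count >= eff.gross.head_count
        assert eff.net.gap >= eff.gross.gap


def test_measures_monotone_in_poverty_line(rng):
    ds = random_dataset(rng, 200)
    y = ds.total_expenditure / ds.size
    lines = [PovertyLine(float(np.quantile(y, q))) for q in (0.1, 0.3, 0.5, 0.8)]
    hcs = [poverty_head_count(ds, pl) for pl in lines]
    gaps = [poverty_gap(ds, pl)[0] for pl in lines]
    assert hcs == sorted(hcs)
    assert gaps == sorted(gaps)


def test_consistency_identities(rng):
    ds = random_dataset(rng, 250)
    line = PovertyLine(float(np.quantile(ds.total_expenditure / ds.size, 0.4)))
    for basis in ("gross", "net"):
        res = poverty_measures(ds, line, basis)
        assert res.normalized_gap * line.value == pytest.approx(res.gap, abs=1e-12 * line.value)
        if res.head_count > 0:
            assert res.normalized_mean_positive_gap * res.head_count == pytest.approx(
                res.normalized_gap, abs=1e-12
            )


def test_person_expansion_oracle(rng):
    """Person-weighted household sums equal literal expansion into individuals."""
    for n in (5, 40, 100):
        ds = random_dataset(rng, n)
        y_gross, y_net = expand_to_persons(ds)
        line = PovertyLine(float(np.quantile(y_gross, 0.5)))
        for basis, y in (("gross", y_gross), ("net", y_net)):
            poor = y < line.value
            assert poverty_head_count(ds, line, basis) == pytest.approx(
                poor.mean(), abs=1e-15
            )
            gap, ng, _ = poverty_gap(ds, line, basis)
            assert gap == pytest.approx(
                np.where(poor, line.value - y, 0.0).mean(), rel=1e-14
            )


def test_sampling_weights_scale_person_weights():
    # doubling a household's weight is the same as duplicating it
    base = make_dataset([180.0, 150.0], [50.0, 50.0], [0.0, 0.0], size=[2, 1],
                        weight=[2.0, 1.0])
    dup = make_dataset([180.0, 180.0, 150.0], [50.0] * 3, [0.0] * 3, size=[2, 2, 1])
    assert poverty_head_count(base, PL100) == pytest.approx(poverty_head_count(dup, PL100))


def test_impoverished_population_projection():
    assert impoverished_population(0.01, 1_000_000) == 10_000
    assert impoverished_population(0.0, 123) == 0
    with pytest.raises(InputError):
        impoverished_population(0.01, 0)


def test_poverty_line_presets_and_validation():
    assert POVERTY_LINE_PRESETS["mongolia_national_2012"].value == 118_668.0
    assert POVERTY_LINE_PRESETS["worldbank_190ppp_2012"].value == 34_769.6
    with pytest.raises(InputError):
        PovertyLine(0.0)
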