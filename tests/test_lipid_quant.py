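"""Internal-standard quantification, IP subtraction and lipid indices."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gdgtbudget.errors import DataError, UndefinedResultError
from gdgtbudget.lipid_quant import (
    FLAG_ABSENT,
    FLAG_BELOW_LOQ,
    FLAG_FAILED_SN,
    FLAG_OK,
    PeakRecord,
    QuantConfig,
    build_profile,
    frame_to_records,
    ipl_class_distribution,
    quantify_core,
    read_peak_table,
    signal_to_noise,
    tex86,
    write_peak_table,
)


def rec(compound="crenarchaeol", fraction="hydrolyzed", cls="core", adduct="M+NH4",
        area=1.0, noise=0.001, is_area=1.0, is_mass=5.0, vol=20.0, sample="S1"):
    return PeakRecord(
        sample_id=sample, fraction=fraction, compound=compound,
        headgroup_class=cls, adduct=adduct, peak_area=area,
        noise_level=noise, is_area=is_area, is_mass_ng=is_mass, volume_L=vol,
    )


class TestSignalToNoise:
    @pytest.mark.parametrize("area,noise,expected", [
        (10.0, 2.0, 5.0),
        (0.0, 1.0, 0.0),
        (7.5, 1.5, 5.0),
    ])
    def test_ratio(self, area, noise, expected):
        assert signal_to_noise(area, noise) == pytest.approx(expected)

    def test_boundary_passes_inclusively(self):
        conc, flag = quantify_core(rec(area=7.5, noise=1.5), QuantConfig())
        assert flag in (FLAG_OK, FLAG_BELOW_LOQ)  # SN exactly 5 is reported
        assert conc > 0

    def test_invalid_noise(self):
        with pytest.raises(DataError, match="invalid noise"):
            signal_to_noise(1.0, 0.0)


class TestQuantifyCore:
    @pytest.mark.parametrize("compound,area,is_mass,expected", [
        ("crenarchaeol", 2.0, 5.0, 0.75),   # (2/1) * 1.5 * 5 / 20
        ("archeol", 1.0, 4.0, 0.8),         # (1/1) * 4.0 * 4 / 20
    ])
    def test_hand_arithmetic(self, compound, area, is_mass, expected):
        conc, flag = quantify_core(rec(compound=compound, area=area, is_mass=is_mass))
        assert conc == pytest.approx(expected)
        assert flag == FLAG_OK

    def test_zero_area_is_absent(self):
        assert quantify_core(rec(area=0.0)) == (0.0, FLAG_ABSENT)

    def test_failed_sn_zeroes_with_distinct_flag(self):
        conc, flag = quantify_core(rec(area=1.0, noise=1.0))
        assert (conc, flag) == (0.0, FLAG_FAILED_SN)

    def test_below_loq_keeps_value(self):
        # conc = 1e-4/1 * 1.5 * 5 / 20 = 3.75e-5 < 0.00060, SN fine
        conc, flag = quantify_core(rec(area=1e-4, noise=1e-9))
        assert flag == FLAG_BELOW_LOQ
        assert conc == pytest.approx(3.75e-5)

    def test_internal_standard_rejected(self):
        with pytest.raises(DataError):
            quantify_core(rec(compound="C46-standard"))

    def test_unknown_compound_rejected(self):
        with pytest.raises(DataError, match="unknown compound"):
            QuantConfig().response_factor("GDGT-9")

    @given(scale=st.floats(0.1, 100), vol=st.floats(1.0, 100.0))
    def test_linear_in_area_inverse_in_volume(self, scale, vol):
        base, _ = quantify_core(rec(area=1.0, vol=vol))
        scaled, _ = quantify_core(rec(area=scale, vol=vol))
        assert scaled == pytest.approx(scale * base, rel=1e-12)
        half_vol, _ = quantify_core(rec(area=1.0, vol=vol / 2))
        assert half_vol == pytest.approx(2 * base, rel=1e-12)


class TestBuildProfile:
    def pair(self, total_area, core_area, compound="crenarchaeol"):
        return [
            rec(compound=compound, fraction="hydrolyzed", area=total_area),
            rec(compound=compound, fraction="non_hydrolyzed", area=core_area),
        ]

    def test_subtraction(self):
        # areas chosen so conc = area * 0.375 -> total 0.015, core 0.005
        p = build_profile(self.pair(0.04, 0.04 / 3))
        assert p.total_conc["crenarchaeol"] == pytest.approx(0.015)
        assert p.ip_conc["crenarchaeol"] == pytest.approx(0.010)
        assert p.ip_total == pytest.approx(0.010)

    def test_negative_ip_retained_but_clamped_in_total(self):
        p = build_profile(self.pair(0.008, 0.04 / 3))  # total 0.003 < core 0.005
        assert p.ip_conc["crenarchaeol"] == pytest.approx(-0.002)
        assert p.ip_total == 0.0

    def test_identical_fractions_give_zero_ip(self):
        p = build_profile(self.pair(0.04, 0.04))
        assert p.ip_conc["crenarchaeol"] == pytest.approx(0.0, abs=1e-15)
        assert p.ip_total == pytest.approx(0.0, abs=1e-15)

    def test_missing_compounds_absent(self):
        p = build_profile(self.pair(0.04, 0.01))
        assert p.flags["GDGT-0"] == FLAG_ABSENT
        assert p.total_conc["GDGT-0"] == 0.0

    def test_ip_identity_per_compound(self):
        p = build_profile(self.pair(0.05, 0.01) + self.pair(0.02, 0.03, "GDGT-2"))
        for c in p.ip_conc:
            assert p.ip_conc[c] == pytest.approx(p.total_conc[c] - p.core_conc[c], rel=1e-12)

    def test_order_invariance(self):
        records = (self.pair(0.05, 0.01) + self.pair(0.02, 0.03, "GDGT-2")
                   + self.pair(0.01, 0.002, "archeol"))
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        assert build_profile(records).ip_total == build_profile(shuffled).ip_total
        assert build_profile(records).ip_total >= 0

    def test_duplicate_keys_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            build_profile([rec(area=1.0), rec(area=2.0)])

    def test_mixed_samples_rejected(self):
        with pytest.raises(DataError, match="mixed sample_ids"):
            build_profile([rec(sample="S1"), rec(sample="S2", fraction="non_hydrolyzed")])

    def test_max_area_adduct_selected(self):
        p = build_profile([
            rec(area=0.04, adduct="M+NH4"),
            rec(area=0.08, adduct="M+Na"),
            rec(area=0.01, adduct="M+H"),
        ])
        assert p.total_conc["crenarchaeol"] == pytest.approx(0.08 * 0.375)


class TestIplClassDistribution:
    def test_single_compound(self):
        records = [rec(fraction="non_hydrolyzed", cls="HPH", area=100.0)]
        assert ipl_class_distribution(records) == {"HPH": {"crenarchaeol": 1.0}}

    def test_equal_split(self):
        records = [
            rec("GDGT-1", "non_hydrolyzed", "HPH", area=50.0),
            rec("crenarchaeol", "non_hydrolyzed", "HPH", area=50.0),
        ]
        dist = ipl_class_distribution(records)["HPH"]
        assert dist == {"GDGT-1": 0.5, "crenarchaeol": 0.5}

    def test_proportions(self):
        records = [
            rec("GDGT-2", "non_hydrolyzed", "DH", area=30.0),
            rec("crenarchaeol-isomer", "non_hydrolyzed", "DH", area=60.0),
            rec("GDGT-0", "non_hydrolyzed", "DH", area=10.0),
        ]
        dist = ipl_class_distribution(records)["DH"]
        assert dist == pytest.approx(
            {"GDGT-2": 0.3, "crenarchaeol-isomer": 0.6, "GDGT-0": 0.1})
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_input(self):
        assert ipl_class_distribution([]) == {}

    def test_archeol_limited_to_monohexose(self):
        with pytest.raises(DataError, match="monohexose"):
            rec("archeol", "non_hydrolyzed", "DH", area=1.0)


class TestTex86:
    def test_symmetric(self):
        concs = {"GDGT-1": 1.0, "GDGT-2": 1.0, "GDGT-3": 1.0, "crenarchaeol-isomer": 1.0}
        assert tex86(concs) == pytest.approx(0.75)

    def test_hand_arithmetic(self):
        concs = {"GDGT-1": 2.0, "GDGT-2": 1.0, "GDGT-3": 1.0, "crenarchaeol-isomer": 1.0}
        assert tex86(concs) == pytest.approx(0.6)

    def test_boundary(self):
        concs = {"GDGT-1": 1.0, "GDGT-2": 0.0, "GDGT-3": 0.0, "crenarchaeol-isomer": 0.0}
        assert tex86(concs) == 0.0

    def test_zero_denominator_signalled(self):
        with pytest.raises(UndefinedResultError):
            tex86({"GDGT-1": 0.0, "GDGT-2": 0.0, "GDGT-3": 0.0, "crenarchaeol-isomer": 0.0})

    @given(k=st.floats(1e-6, 1e6))
    def test_scale_invariance(self, k):
        concs = {"GDGT-1": 2.0, "GDGT-2": 1.0, "GDGT-3": 0.5, "crenarchaeol-isomer": 1.5}
        scaled = {c: k * v for c, v in concs.items()}
        assert tex86(scaled) == pytest.approx(tex86(concs), rel=1e-9)


def test_peak_table_roundtrip(tmp_path, default_dataset):
    """A profile built from a peak table equals the one built after a
    write/read round trip of that table."""
    records = [r for r in default_dataset.peak_records() if r.sample_id == "SYN1_125m"]
    path = tmp_path / "peaks.csv"
    write_peak_table(records, str(path))
    back = read_peak_table(str(path))
    p1, p2 = build_profile(records), build_profile(back)
    assert p1 == p2


def test_frame_missing_columns_rejected():
    import pandas as pd
    with pytest.raises(DataError, match="missing columns"):
        frame_to_records(pd.DataFrame({"sample_id": ["S1"]}))


def test_tex86_finite_on_synthetic_cores(default_profiles):
    for p in default_profiles:
        if sum(p.core_conc.get(c, 0) for c in
               ("GDGT-1", "GDGT-2", "GDGT-3", "crenarchaeol-isomer")) > 0:
            assert 0.0 <= tex86(p.core_conc) <= 1.0
            assert math.isfinite(tex86(p.core_conc))
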