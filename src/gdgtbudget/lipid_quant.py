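"""Quantification of archaeal ether lipids from LC-MS SIM peak tables.

Converts per-sample selected-ion-monitoring peak areas into core- and
intact-polar-lipid (IP) concentrations in ng/L, using single-point internal
standard (C46) quantification with compound-class response factors:

    conc = (A_analyte / A_IS) * RF * m_IS / V

where ``A`` are peak areas, ``m_IS`` the spiked internal-standard mass (ng)
and ``V`` the filtered seawater volume (L). RF > 1 means the analyte responds
more weakly than C46; the defaults are 1.5 for tetraethers (calibrated on
crenarchaeol) and 4.0 for archeol.

IP concentrations are obtained by subtraction: the acid-hydrolyzed fraction
measures total (core + IP, head groups cleaved) lipid, the non-hydrolyzed
fraction measures pre-existing core lipid, and their difference is the intact
polar pool. Per-compound differences may be negative (matrix effects differ
between fractions); negatives are retained per compound but clamped to zero
when summing to the per-sample IP total. Peaks with a signal-to-noise ratio
below the threshold (default 5, inclusive pass at the boundary) contribute
zero; concentrations below the limit of quantification (default 0.00060 ng/L)
are reported with their computed value plus a ``below_loq`` flag.

Head-group-specific GDGT forms (MH/DH/PH/HPH) lack authentic standards and
are reported only as within-class relative peak-area distributions.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .compounds import (
    ADDUCTS,
    ANALYTES,
    ARCHEOL,
    CRENARCHAEOL_ISOMER,
    FRACTIONS,
    GDGT_1,
    GDGT_2,
    GDGT_3,
    HEADGROUP_CLASSES,
    INTERNAL_STANDARD,
    is_gdgt,
)
from .errors import ConfigError, DataError, UndefinedResultError

FLAG_OK = "ok"
FLAG_BELOW_LOQ = "below_loq"
FLAG_FAILED_SN = "failed_sn"
FLAG_ABSENT = "absent"

PEAK_COLUMNS = [
    "sample_id",
    "fraction",
    "compound",
    "headgroup_class",
    "adduct",
    "peak_area",
    "noise_level",
    "is_area",
    "is_mass_ng",
    "volume_L",
]


@dataclass(frozen=True)
class QuantConfig:
    """Quantification rules: response factors, SN threshold, LOQ."""

    rf_crenarchaeol: float = 1.5
    rf_archeol: float = 4.0
    sn_threshold: float = 5.0
    loq_ng_per_L: float = 0.00060

    def __post_init__(self):
        for name in ("rf_crenarchaeol", "rf_archeol", "sn_threshold", "loq_ng_per_L"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"QuantConfig.{name} must be strictly positive")

    def response_factor(self, compound: str) -> float:
        """RF for a compound: archeol gets its own; all GDGTs share the
        crenarchaeol-calibrated factor (exactly two factors are applied)."""
        if compound == ARCHEOL:
            return self.rf_archeol
        if is_gdgt(compound):
            return self.rf_crenarchaeol
        if compound == INTERNAL_STANDARD:
            raise DataError("the C46 internal standard is not an analyte")
        raise DataError(f"unknown compound: {compound!r}")


@dataclass(frozen=True)
class PeakRecord:
    """One SIM peak measurement with its internal-standard reference."""

    sample_id: str
    fraction: str
    compound: str
    headgroup_class: str
    adduct: str
    peak_area: float
    noise_level: float
    is_area: float
    is_mass_ng: float
    volume_L: float

    def __post_init__(self):
        if self.fraction not in FRACTIONS:
            raise DataError(f"invalid fraction {self.fraction!r}")
        if self.headgroup_class not in HEADGROUP_CLASSES:
            raise DataError(f"invalid headgroup class {self.headgroup_class!r}")
        if self.adduct not in ADDUCTS:
            raise DataError(f"invalid adduct {self.adduct!r}")
        if self.headgroup_class != "core" and self.fraction != "non_hydrolyzed":
            raise DataError("intact polar classes are valid only in the non-hydrolyzed fraction")
        if self.compound == ARCHEOL and self.headgroup_class not in ("core", "MH"):
            raise DataError("archeol intact polar form is limited to monohexose (MH)")
        if not self.peak_area >= 0:
            raise DataError("peak_area must be >= 0")
        if not self.noise_level >= 0:
            raise DataError("noise_level must be >= 0")
        if not self.is_area > 0:
            raise DataError("is_area must be > 0")
        if not self.is_mass_ng > 0:
            raise DataError("is_mass_ng must be > 0")
        if not self.volume_L > 0:
            raise DataError("volume_L must be > 0")


@dataclass
class LipidProfile:
    """Per-sample ether lipid concentrations (ng/L) and derived IP pools.

    ``ip_conc`` retains per-compound negatives from the fraction subtraction;
    ``ip_total`` clamps them at zero before summing.
    """

    sample_id: str
    core_conc: dict[str, float]
    total_conc: dict[str, float]
    ip_conc: dict[str, float]
    ip_total: float
    ipl_class_distribution: dict[str, dict[str, float]]
    flags: dict[str, str] = field(default_factory=dict)


def signal_to_noise(peak_area: float, noise_level: float) -> float:
    """Peak signal-to-noise ratio; the reporting threshold passes inclusively."""
    if not noise_level > 0:
        raise DataError("invalid noise")
    if peak_area < 0:
        raise DataError("peak_area must be >= 0")
    return peak_area / noise_level


def quantify_core(rec: PeakRecord, cfg: QuantConfig | None = None) -> tuple[float, str]:
    """Quantify one core-lipid peak against the C46 internal standard.

    Returns ``(concentration_ng_per_L, flag)``. A peak failing the SN
    threshold contributes zero concentration but keeps its distinct
    ``failed_sn`` flag; a quantified value below the LOQ is reported as-is
    with ``below_loq``.
    """
    cfg = cfg or QuantConfig()
    if rec.compound == INTERNAL_STANDARD:
        raise DataError("the C46 internal standard is not an analyte")
    rf = cfg.response_factor(rec.compound)
    if rec.peak_area == 0:
        return 0.0, FLAG_ABSENT
    if signal_to_noise(rec.peak_area, rec.noise_level) < cfg.sn_threshold:
        return 0.0, FLAG_FAILED_SN
    conc = (rec.peak_area / rec.is_area) * rf * rec.is_mass_ng / rec.volume_L
    flag = FLAG_BELOW_LOQ if conc < cfg.loq_ng_per_L else FLAG_OK
    return conc, flag


def _best_adduct(records: Iterable[PeakRecord]) -> dict[tuple[str, str, str], PeakRecord]:
    """Pick the maximum-area adduct per (fraction, compound, class)."""
    best: dict[tuple[str, str, str], PeakRecord] = {}
    for r in records:
        k = (r.fraction, r.compound, r.headgroup_class)
        if k not in best or r.peak_area > best[k].peak_area:
            best[k] = r
    return best


def build_profile(records: Sequence[PeakRecord], cfg: QuantConfig | None = None) -> LipidProfile:
    """Assemble a :class:`LipidProfile` from one sample's peak records.

    Core concentrations come from the non-hydrolyzed fraction, totals from the
    acid-hydrolyzed fraction, and IP = total - core per compound (negatives
    retained; clamped only in ``ip_total``). Missing compounds are reported as
    zero with an ``absent`` flag. Flags follow the hydrolyzed (total)
    measurement, which defines the reported concentration.
    """
    cfg = cfg or QuantConfig()
    if not records:
        raise DataError("no peak records")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise DataError(f"mixed sample_ids in one profile: {sorted(sample_ids)}")
    keys = [(r.fraction, r.compound, r.headgroup_class, r.adduct) for r in records]
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise DataError(f"duplicate peak records for {dupes}")
    for r in records:
        if r.compound == INTERNAL_STANDARD:
            raise DataError("the C46 internal standard is not an analyte")

    best = _best_adduct(records)
    core_conc: dict[str, float] = {}
    total_conc: dict[str, float] = {}
    flags: dict[str, str] = {}
    for c in ANALYTES:
        rec_tot = best.get(("hydrolyzed", c, "core"))
        rec_core = best.get(("non_hydrolyzed", c, "core"))
        total_conc[c], flag_tot = quantify_core(rec_tot, cfg) if rec_tot else (0.0, FLAG_ABSENT)
        core_conc[c], _ = quantify_core(rec_core, cfg) if rec_core else (0.0, FLAG_ABSENT)
        flags[c] = flag_tot

    ip_conc = {c: total_conc[c] - core_conc[c] for c in ANALYTES}
    ip_total = sum(max(v, 0.0) for v in ip_conc.values())
    return LipidProfile(
        sample_id=next(iter(sample_ids)),
        core_conc=core_conc,
        total_conc=total_conc,
        ip_conc=ip_conc,
        ip_total=ip_total,
        ipl_class_distribution=ipl_class_distribution(records),
        flags=flags,
    )


def ipl_class_distribution(records: Iterable[PeakRecord]) -> dict[str, dict[str, float]]:
    """Relative peak-area distribution of compounds within each IP class.

    Uses only non-hydrolyzed, non-core records (the head-group-specific forms
    that cannot be absolutely quantified). Classes with zero total area are
    omitted; an empty input yields an empty map.
    """
    ipl = [r for r in records if r.fraction == "non_hydrolyzed" and r.headgroup_class != "core"]
    best = _best_adduct(ipl)
    by_class: dict[str, dict[str, float]] = {}
    for (_, compound, cls), rec in best.items():
        by_class.setdefault(cls, {})[compound] = rec.peak_area
    out: dict[str, dict[str, float]] = {}
    for cls, areas in by_class.items():
        total = sum(areas.values())
        if total > 0:
            out[cls] = {c: a / total for c, a in areas.items()}
    return out


def tex86(core_concs: Mapping[str, float]) -> float:
    """TEX86 ring index from core GDGT concentrations.

    (GDGT-2 + GDGT-3 + cren') / (GDGT-1 + GDGT-2 + GDGT-3 + cren') where
    cren' is the crenarchaeol regioisomer. Scale-invariant; undefined when
    the denominator is zero.
    """
    g1 = core_concs.get(GDGT_1, 0.0)
    g2 = core_concs.get(GDGT_2, 0.0)
    g3 = core_concs.get(GDGT_3, 0.0)
    iso = core_concs.get(CRENARCHAEOL_ISOMER, 0.0)
    if min(g1, g2, g3, iso) < 0:
        raise DataError("negative concentration in TEX86 input")
    denom = g1 + g2 + g3 + iso
    if denom == 0:
        raise UndefinedResultError("TEX86 undefined: all ring GDGTs are zero")
    return (g2 + g3 + iso) / denom


# ---------------------------------------------------------------------------
# Tabular IO

def records_to_frame(records: Sequence[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in PEAK_COLUMNS} for r in records],
                        columns=PEAK_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PeakRecord]:
    missing = [c for c in PEAK_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"peak table missing columns: {missing}")
    return [
        PeakRecord(
            sample_id=str(row.sample_id),
            fraction=str(row.fraction),
            compound=str(row.compound),
            headgroup_class=str(row.headgroup_class),
            adduct=str(row.adduct),
            peak_area=float(row.peak_area),
            noise_level=float(row.noise_level),
            is_area=float(row.is_area),
            is_mass_ng=float(row.is_mass_ng),
            volume_L=float(row.volume_L),
        )
        for row in frame.itertuples(index=False)
    ]


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_peak_table(path: str) -> list[PeakRecord]:
    """Read a CSV/TSV peak table (UTF-8, dot decimal separator)."""
    return frame_to_records(
        pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip"))


def write_peak_table(records: Sequence[PeakRecord], path: str) -> None:
    # %.17g keeps every float bit, so a written table reads back identically
    records_to_frame(records).to_csv(path, sep=_sep_for(path), index=False,
                                     float_format="%.17g")


def build_profiles(records: Sequence[PeakRecord], cfg: QuantConfig | None = None) -> list[LipidProfile]:
    """Group a multi-sample peak list by sample (input order preserved)."""
    by_sample: dict[str, list[PeakRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    return [build_profile(recs, cfg) for recs in by_sample.values()]


def profiles_to_frame(profiles: Sequence[LipidProfile]) -> pd.DataFrame:
    """Long-format profile table: one row per (sample, compound)."""
    rows = []
    for p in profiles:
        for c in ANALYTES:
            rows.append({
                "sample_id": p.sample_id,
                "compound": c,
                "core_ng_per_L": p.core_conc[c],
                "total_ng_per_L": p.total_conc[c],
                "ip_ng_per_L": p.ip_conc[c],
                "flag": p.flags[c],
            })
    return pd.DataFrame(rows)


def class_distribution_frame(profiles: Sequence[LipidProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for cls, dist in p.ipl_class_distribution.items():
            for c, frac in dist.items():
                rows.append({
                    "sample_id": p.sample_id,
                    "headgroup_class": cls,
                    "compound": c,
                    "fraction_of_class": frac,
                })
    return pd.DataFrame(rows, columns=["sample_id", "headgroup_class", "compound", "fraction_of_class"])
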