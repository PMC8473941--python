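"""Mass-balance attribution of intact polar ether lipids to archaeal groups.

The central model links measured intact-polar (IP) ether lipid pools to
absolute archaeal cell densities through per-cell lipid quotas (ng/cell):

* quota      = IP pool / cells                     (per-sample estimate)
* pool       = cells x quota                       (expected pool per taxon)
* cells      = IP pool / quota                     (inferred source abundance)
* fraction   = pool(taxon) / sum of pools          (attribution)

Where the amplicon survey detects only Thermoplasmatota (MGII/III), dividing
the IP-ether pool by their cell density yields an apparent Thermoplasmatota
quota; comparing it to the theoretical whole-membrane lipid content of a
500-nm archaeal cell (1.4e-6 ng/cell) bounds the fraction of the membrane the
measured ethers could represent. Conversely, dividing the same pool by the
published Thaumarchaeota quota (1.27e-6 ng/cell) infers how many
Thaumarchaeota would be needed to explain the lipids; comparing that
abundance to the per-sample sequencing detection limit decides whether such a
population should have been visible in the amplicon data.

All verdict boundaries are inclusive (>=).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import (
    THAUMARCHAEOTA,
    THERMOPLASMATOTA_GROUPS,
    TaxonAbundanceProfile,
    detection_limit,
)
from .errors import ConfigError, DataError, UndefinedResultError
from .lipid_quant import FLAG_OK, LipidProfile

THERMOPLASMATOTA_POOL = "MGII/III"


@dataclass(frozen=True)
class BudgetParameters:
    """Conversion factors of the mass-balance model.

    quota_thaumarchaeota: published per-cell ether lipid content of cultured
        Thaumarchaeota, ng/cell.
    quota_theoretical_membrane: total lipid of a 500-nm-diameter archaeal
        cell, ng/cell; denominator of :func:`membrane_fraction`.
    copy_number: SSU rRNA gene copies per cell (1 for the marine planktonic
        groups modelled here).
    min_group_fraction: groups below this relative abundance are excluded
        from expected pools (e.g. trace Halobacterota).
    """

    quota_thaumarchaeota: float = 1.27e-6
    quota_theoretical_membrane: float = 1.4e-6
    copy_number: float = 1.0
    min_group_fraction: float = 0.01

    def __post_init__(self):
        for name in ("quota_thaumarchaeota", "quota_theoretical_membrane", "copy_number"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"BudgetParameters.{name} must be strictly positive")
        if not 0 <= self.min_group_fraction < 1:
            raise ConfigError("BudgetParameters.min_group_fraction must be in [0, 1)")


def per_cell_quota(ip_total: float, cells_per_L: float) -> float:
    """Per-cell lipid quota (ng/cell) = IP pool (ng/L) / cells (cells/L)."""
    if ip_total < 0:
        raise DataError("ip_total must be >= 0")
    if not cells_per_L > 0:
        raise DataError("undefined quota: zero cells")
    return ip_total / cells_per_L


def expected_pool(cells_per_L: float, quota: float) -> float:
    """Expected lipid pool (ng/L) = cells (cells/L) x quota (ng/cell)."""
    if cells_per_L < 0 or quota < 0:
        raise DataError("cells and quota must be >= 0")
    return cells_per_L * quota


def infer_cells(ip_total: float, quota: float) -> float:
    """Cell density (cells/L) required to explain an IP pool at a given quota."""
    if ip_total < 0:
        raise DataError("ip_total must be >= 0")
    if not quota > 0:
        raise DataError("quota must be > 0")
    return ip_total / quota


def membrane_fraction(quota: float, params: BudgetParameters | None = None) -> float:
    """Quota as a percentage of the theoretical whole-membrane lipid content."""
    params = params or BudgetParameters()
    if quota < 0:
        raise DataError("quota must be >= 0")
    return 100.0 * quota / params.quota_theoretical_membrane


def attribute(expected_pools: Mapping[str, float]) -> dict[str, float]:
    """Fraction of the total expected pool attributable to each taxon."""
    for t, v in expected_pools.items():
        if v < 0:
            raise DataError(f"negative expected pool for {t!r}")
    total = sum(expected_pools.values())
    if total == 0:
        raise UndefinedResultError("attribution undefined: all expected pools are zero")
    return {t: v / total for t, v in expected_pools.items()}


def measured_vs_expected(measured_ip_total: float, expected_total: float) -> float:
    """Ratio of measured to expected total IP-ether pool."""
    if measured_ip_total < 0:
        raise DataError("measured_ip_total must be >= 0")
    if not expected_total > 0:
        raise UndefinedResultError("measured/expected undefined: expected total is zero")
    return measured_ip_total / expected_total


@dataclass(frozen=True)
class DetectabilityVerdict:
    """Whether an inferred population would exceed the sequencing detection
    limit (inclusive comparison); both sides of the comparison are kept."""

    detectable: bool
    relative_abundance_percent: float
    detection_limit_percent: float


def detectability(
    inferred_cells: float,
    total_copies: float,
    read_depth: int,
    copy_number: float = 1.0,
) -> DetectabilityVerdict:
    """Compare an inferred population's relative abundance to the per-sample
    detection limit (one read)."""
    if inferred_cells < 0:
        raise DataError("inferred_cells must be >= 0")
    if not total_copies > 0:
        raise DataError("total_copies must be > 0")
    if not copy_number > 0:
        raise DataError("copy_number must be > 0")
    limit = detection_limit(read_depth)
    relative = 100.0 * inferred_cells * copy_number / total_copies
    return DetectabilityVerdict(
        detectable=relative >= limit,
        relative_abundance_percent=relative,
        detection_limit_percent=limit,
    )


# ---------------------------------------------------------------------------
# Per-sample orchestration

@dataclass
class SampleBudget:
    sample_id: str
    zone: str  # "surface" (no Thaumarchaeota detected) or "subsurface"
    is_control: bool
    ip_total: float
    thermo_cells: float
    thermo_quota: float | None = None
    membrane_percent: float | None = None
    expected_pools: dict[str, float] = field(default_factory=dict)
    expected_total: float | None = None
    attribution: dict[str, float] = field(default_factory=dict)
    measured_over_expected: float | None = None
    inferred_thaum_cells: float | None = None
    verdict: DetectabilityVerdict | None = None


@dataclass
class BudgetReport:
    samples: list[SampleBudget]
    thermo_quota_min: float | None
    thermo_quota_max: float | None
    thermo_quota_mean: float | None
    thermo_quota_used: float | None
    control_samples: list[str]
    params: BudgetParameters

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append({
                "sample_id": s.sample_id,
                "zone": s.zone,
                "is_control": s.is_control,
                "ip_total_ng_per_L": s.ip_total,
                "thermo_cells_per_L": s.thermo_cells,
                "thermo_quota_ng_per_cell": s.thermo_quota,
                "membrane_percent": s.membrane_percent,
                "expected_MGI_ng_per_L": s.expected_pools.get(THAUMARCHAEOTA),
                "expected_MGII_III_ng_per_L": s.expected_pools.get(THERMOPLASMATOTA_POOL),
                "expected_total_ng_per_L": s.expected_total,
                "attribution_MGII_III": s.attribution.get(THERMOPLASMATOTA_POOL),
                "measured_over_expected": s.measured_over_expected,
                "inferred_thaum_cells_per_L": s.inferred_thaum_cells,
                "relative_abundance_percent": s.verdict.relative_abundance_percent if s.verdict else None,
                "detection_limit_percent": s.verdict.detection_limit_percent if s.verdict else None,
                "detectable": s.verdict.detectable if s.verdict else None,
            })
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Ether lipid mass-balance report", "=" * 32]
        q = (self.thermo_quota_min, self.thermo_quota_max, self.thermo_quota_mean)
        if all(v is not None for v in q):
            lines.append(
                f"Surface Thermoplasmatota quota: {q[0]:.3g} to {q[1]:.3g} ng/cell "
                f"(mean {q[2]:.3g}; n={sum(1 for s in self.samples if s.thermo_quota is not None)})"
            )
        if self.control_samples:
            lines.append(f"Control-like samples (no quantifiable lipid peak): {', '.join(self.control_samples)}")
        for s in self.samples:
            lines.append("")
            lines.append(f"[{s.zone}] {s.sample_id}  IP-ethers {s.ip_total:.3g} ng/L")
            if s.is_control:
                lines.append("  excluded from quota summaries (control-like)")
            if s.thermo_quota is not None:
                lines.append(
                    f"  quota {s.thermo_quota:.3g} ng/cell = {s.membrane_percent:.3g}% of theoretical membrane"
                )
            if s.expected_total is not None:
                att = s.attribution.get(THERMOPLASMATOTA_POOL)
                lines.append(
                    f"  expected pool {s.expected_total:.3g} ng/L"
                    + (f"; MGII/III attribution {100 * att:.3g}%" if att is not None else "")
                    + (f"; measured/expected {s.measured_over_expected:.3g}"
                       if s.measured_over_expected is not None else "")
                )
            if s.verdict is not None:
                v = s.verdict
                lines.append(
                    f"  inferred Thaumarchaeota {s.inferred_thaum_cells:.3g} copies/L -> "
                    f"{v.relative_abundance_percent:.3g}% vs limit {v.detection_limit_percent:.3g}% "
                    f"({'detectable' if v.detectable else 'not detectable'})"
                )
        return "\n".join(lines)


def compute_budget(
    lipid_profiles: Sequence[LipidProfile],
    taxon_profiles: Sequence[TaxonAbundanceProfile],
    params: BudgetParameters | None = None,
    thermo_quota: float | None = None,
) -> BudgetReport:
    """Run the full mass-balance model over matched samples.

    Samples where Thaumarchaeota are undetectable (zero copies) are treated
    as "surface": each yields a per-sample Thermoplasmatota quota
    (IP pool / Thermoplasmatota cells) and an inferred Thaumarchaeota
    abundance with its detectability verdict. Samples with Thaumarchaeota
    present are "subsurface": expected pools per source taxon, attribution
    fractions and the measured/expected ratio are computed there, using the
    mean surface quota for MGII/III unless ``thermo_quota`` overrides it.

    Samples in which no compound passed quantification are control-like: the
    model still reports them but excludes them from quota summaries.
    """
    params = params or BudgetParameters()
    lipids = {p.sample_id: p for p in lipid_profiles}
    taxa = {p.sample_id: p for p in taxon_profiles}
    shared = [sid for sid in lipids if sid in taxa]
    if not shared:
        raise DataError("no samples shared between lipid and abundance profiles")

    samples: list[SampleBudget] = []
    quotas: list[float] = []
    controls: list[str] = []
    for sid in shared:
        lp, tp = lipids[sid], taxa[sid]
        thermo_cells = sum(tp.cells_per_L.get(g, 0.0) for g in THERMOPLASMATOTA_GROUPS)
        zone = "surface" if tp.copies_per_L.get(THAUMARCHAEOTA, 0.0) == 0 else "subsurface"
        is_control = not any(f == FLAG_OK for f in lp.flags.values())
        s = SampleBudget(
            sample_id=sid,
            zone=zone,
            is_control=is_control,
            ip_total=lp.ip_total,
            thermo_cells=thermo_cells,
        )
        if is_control:
            controls.append(sid)
        if zone == "surface" and thermo_cells > 0:
            s.thermo_quota = per_cell_quota(lp.ip_total, thermo_cells)
            s.membrane_percent = membrane_fraction(s.thermo_quota, params)
            if not is_control:
                quotas.append(s.thermo_quota)
            s.inferred_thaum_cells = infer_cells(lp.ip_total, params.quota_thaumarchaeota)
            if tp.total_copies_per_L > 0:
                s.verdict = detectability(
                    s.inferred_thaum_cells, tp.total_copies_per_L,
                    tp.read_depth, params.copy_number,
                )
        samples.append(s)

    q_min = min(quotas) if quotas else None
    q_max = max(quotas) if quotas else None
    q_mean = float(np.mean(quotas)) if quotas else None
    q_used = thermo_quota if thermo_quota is not None else q_mean

    for s in samples:
        if s.zone != "subsurface":
            continue
        tp = taxa[s.sample_id]
        total = tp.total_copies_per_L
        pools: dict[str, float] = {}
        thaum_cells = tp.cells_per_L.get(THAUMARCHAEOTA, 0.0)
        if total > 0 and tp.copies_per_L.get(THAUMARCHAEOTA, 0.0) / total >= params.min_group_fraction:
            pools[THAUMARCHAEOTA] = expected_pool(thaum_cells, params.quota_thaumarchaeota)
        thermo_frac = sum(tp.copies_per_L.get(g, 0.0) for g in THERMOPLASMATOTA_GROUPS) / total if total else 0.0
        if q_used is not None and thermo_frac >= params.min_group_fraction:
            pools[THERMOPLASMATOTA_POOL] = expected_pool(s.thermo_cells, q_used)
        s.expected_pools = pools
        s.expected_total = sum(pools.values()) if pools else None
        try:
            s.attribution = attribute(pools) if pools else {}
        except UndefinedResultError:
            s.attribution = {}
        if s.expected_total:
            try:
                s.measured_over_expected = measured_vs_expected(s.ip_total, s.expected_total)
            except UndefinedResultError:
                s.measured_over_expected = None

    return BudgetReport(
        samples=samples,
        thermo_quota_min=q_min,
        thermo_quota_max=q_max,
        thermo_quota_mean=q_mean,
        thermo_quota_used=q_used,
        control_samples=controls,
        params=params,
    )
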