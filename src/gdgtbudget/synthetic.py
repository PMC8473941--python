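"""Synthetic depth-profile datasets with known ground truth.

Emulates the statistical structure of a stratified open-ocean euphotic-zone
survey: two clusters of samples split at the deep chlorophyll maximum (DCM).
Above the DCM only Thermoplasmatota (MGII/MGIII, plus trace minor groups)
are present and total ether lipid concentrations are two to three orders of
magnitude lower; within and below the DCM MGI Thaumarchaeota appear and
dominate the lipid pool through their ~1000-fold larger per-cell quota.

The forward model per sample:

1. A ddPCR total (copies/L) is drawn uniformly from the cluster's range and
   partitioned among archaeal groups by a Dirichlet-jittered cluster
   composition; groups absent from the cluster composition (Thaumarchaeota
   above the DCM) are structural zeros. Cells = copies (one rRNA copy/cell).
2. AASV counts are multinomial draws at a uniform read depth, over per-group
   AASV weights fixed per dataset.
3. True intact-polar lipid pools are cells x quota per producing taxon,
   spread over compounds by per-taxon signatures; the hydrolyzed-fraction
   (total) pool is IP / ip_fraction, and core = total - IP.
4. Peak areas invert the internal-standard quantification formula
   (area = conc x V / (RF x m_IS) x A_IS) with multiplicative lognormal
   noise. The non-hydrolyzed fraction receives extra "matrix effect" noise,
   which is what produces occasional negative per-compound IP estimates
   after subtraction, concentrated above the DCM where the core:IP ratio is
   high. The SIM noise floor is set so a peak at 5e-5 ng/L has SN exactly 5:
   below the LOQ, so near-LOQ peaks can pass the SN filter and be flagged
   ``below_loq`` rather than dropped.

Everything is reproducible from the seed: identical config + seed gives
byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import GROUPS, THAUMARCHAEOTA
from .compounds import ANALYTES, ARCHEOL, IPL_CLASSES
from .errors import ConfigError
from .lipid_quant import PEAK_COLUMNS, PeakRecord, QuantConfig, frame_to_records

ABOVE = "above_dcm"
BELOW = "within_below_dcm"

_THERMO_SIGNATURE = {
    "GDGT-0": 0.45, "GDGT-1": 0.05, "GDGT-2": 0.08, "GDGT-3": 0.03,
    "crenarchaeol": 0.25, "crenarchaeol-isomer": 0.04, "archeol": 0.10,
}
_THAUM_SIGNATURE = {
    "GDGT-0": 0.22, "GDGT-1": 0.05, "GDGT-2": 0.07, "GDGT-3": 0.03,
    "crenarchaeol": 0.50, "crenarchaeol-isomer": 0.05, "archeol": 0.08,
}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the generator.

    Defaults follow the study conditions being emulated: surface ddPCR
    totals 2.11e6-6.02e6 copies/L, deeper totals up to 1.22e7, read depths
    1,695-40,915, Thaumarchaeota quota 1.27e-6 ng/cell, Thermoplasmatota
    quota 1.21e-9 ng/cell, DCM at 120 m, and a core-lipid-dominated
    (70% core) pool above the DCM versus 40% core within/below it.
    """

    depths: tuple = (5, 25, 45, 75, 100, 125, 150, 175, 200)
    dcm_depth: float = 120.0
    n_samples: int = 18
    taxon_profiles: dict = field(default_factory=lambda: {
        ABOVE: {"MGII": 0.72, "MGIII": 0.26, "Woesearchaeota": 0.01, "Nanoarchaeota": 0.01},
        BELOW: {"MGI-Thaumarchaeota": 0.40, "MGII": 0.36, "MGIII": 0.22,
                "Halobacterota": 0.008, "Nanoarchaeota": 0.012},
    })
    true_quota: dict = field(default_factory=lambda: {
        "MGI-Thaumarchaeota": 1.27e-6, "MGII": 1.21e-9, "MGIII": 1.21e-9,
    })
    lipid_signature: dict = field(default_factory=lambda: {
        "MGI-Thaumarchaeota": dict(_THAUM_SIGNATURE),
        "MGII": dict(_THERMO_SIGNATURE),
        "MGIII": dict(_THERMO_SIGNATURE),
    })
    ip_fraction: dict = field(default_factory=lambda: {ABOVE: 0.30, BELOW: 0.60})
    headgroup_split: dict = field(default_factory=lambda: {
        "MH": 0.40, "DH": 0.25, "PH": 0.10, "HPH": 0.25,
    })
    total_copies_range: dict = field(default_factory=lambda: {
        ABOVE: (2.11e6, 6.02e6), BELOW: (4.0e6, 1.22e7),
    })
    read_depth_range: dict = field(default_factory=lambda: {
        ABOVE: (1695, 40915), BELOW: (1695, 40915),
    })
    n_aasv_per_group: int = 8
    dirichlet_concentration: float = 200.0
    noise_sigma: float = 0.20
    matrix_effect_sigma: float = 0.30
    noise_floor_ng_per_L: float = 5.0e-5  # concentration at which SN = 5
    volume_L: float = 20.0
    is_mass_ng: float = 5.0
    is_area: float = 1.0e6
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if list(self.depths) != sorted(self.depths):
            raise ConfigError("depths must be sorted ascending")
        for cluster, comp in self.taxon_profiles.items():
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ConfigError(f"taxon profile for {cluster!r} does not sum to 1")
            unknown = set(comp) - set(GROUPS)
            if unknown:
                raise ConfigError(f"unknown groups in taxon profile: {sorted(unknown)}")
        for g, q in self.true_quota.items():
            if not q > 0:
                raise ConfigError(f"true quota for {g!r} must be > 0")
        for g, sig in self.lipid_signature.items():
            if abs(sum(sig.values()) - 1.0) > 1e-9:
                raise ConfigError(f"lipid signature for {g!r} does not sum to 1")
        for cluster, f in self.ip_fraction.items():
            if not 0 < f <= 1:
                raise ConfigError(f"ip_fraction for {cluster!r} must be in (0, 1]")
        if abs(sum(self.headgroup_split.values()) - 1.0) > 1e-9:
            raise ConfigError("headgroup_split does not sum to 1")
        if self.noise_sigma < 0 or self.matrix_effect_sigma < 0:
            raise ConfigError("noise sigmas must be >= 0")
        for name in ("noise_floor_ng_per_L", "volume_L", "is_mass_ng", "is_area"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        for rng_map in (self.total_copies_range, self.read_depth_range):
            for cluster, (lo, hi) in rng_map.items():
                if not 0 < lo <= hi:
                    raise ConfigError(f"invalid range for {cluster!r}: ({lo}, {hi})")


@dataclass
class SyntheticTruth:
    """Ground truth alongside the generated tables, for recovery tests."""

    cells: pd.DataFrame          # samples x groups, cells/L
    ip_conc: pd.DataFrame        # samples x compounds, true IP ng/L
    total_conc: pd.DataFrame     # samples x compounds, true total ng/L
    ip_total: pd.Series          # true per-sample IP-ether sum, ng/L
    quotas: dict                 # group -> ng/cell
    clusters: pd.Series          # sample -> above_dcm | within_below_dcm

    def to_json(self) -> str:
        return json.dumps({
            "cells": self.cells.to_dict(orient="index"),
            "ip_conc": self.ip_conc.to_dict(orient="index"),
            "total_conc": self.total_conc.to_dict(orient="index"),
            "ip_total": self.ip_total.to_dict(),
            "quotas": self.quotas,
            "clusters": self.clusters.to_dict(),
        }, indent=1)


@dataclass
class SyntheticDataset:
    peak_table: pd.DataFrame
    count_table: pd.DataFrame    # rows = AASVs, columns = samples
    taxonomy: pd.Series          # aasv_id -> group
    ddpcr: pd.DataFrame          # sample_id, copies_per_L
    metadata: pd.DataFrame
    truth: SyntheticTruth

    def peak_records(self) -> list[PeakRecord]:
        return frame_to_records(self.peak_table)


def _area_from_conc(conc: float, compound: str, cfg: SyntheticConfig, qc: QuantConfig) -> float:
    """Invert the internal-standard quantification formula."""
    rf = qc.response_factor(compound)
    return conc * cfg.volume_L / (rf * cfg.is_mass_ng) * cfg.is_area


def generate(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a complete dataset (peak, count, ddPCR, metadata tables plus
    ground truth). ``seed`` overrides ``config.seed`` when given."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    qc = QuantConfig()

    # per-dataset AASV weights, fixed across samples so the community has a
    # stable fine-grained structure within each group
    groups_present = sorted({g for comp in cfg.taxon_profiles.values() for g in comp})
    aasv_ids: list[str] = []
    aasv_group: list[str] = []
    weights: dict[str, np.ndarray] = {}
    for g in groups_present:
        weights[g] = rng.dirichlet(np.full(cfg.n_aasv_per_group, 2.0))
        for k in range(cfg.n_aasv_per_group):
            aasv_ids.append(f"{g}_ASV{k + 1:02d}")
            aasv_group.append(g)

    depths = list(cfg.depths)
    sample_ids, sample_depth, sample_cluster, stations = [], [], [], []
    count_cols: dict[str, np.ndarray] = {}
    ddpcr_rows, peak_rows = [], []
    cells_rows, ip_rows, total_rows = {}, {}, {}

    for k in range(cfg.n_samples):
        depth = depths[k % len(depths)]
        profile = k // len(depths) + 1
        sid = f"SYN{profile}_{depth:03d}m"
        cluster = ABOVE if depth < cfg.dcm_depth else BELOW
        sample_ids.append(sid)
        sample_depth.append(depth)
        sample_cluster.append(cluster)
        stations.append(f"SYN{profile}")

        # --- community ---
        lo, hi = cfg.total_copies_range[cluster]
        total_copies = float(rng.uniform(lo, hi))
        base = cfg.taxon_profiles[cluster]
        present = sorted(base)
        alpha = np.array([base[g] for g in present]) * cfg.dirichlet_concentration
        comp = rng.dirichlet(alpha)
        copies = {g: 0.0 for g in groups_present}
        for g, c in zip(present, comp):
            copies[g] = total_copies * float(c)
        cells = dict(copies)  # one SSU rRNA copy per cell

        dlo, dhi = cfg.read_depth_range[cluster]
        read_depth = int(rng.integers(dlo, dhi + 1))
        probs = np.concatenate([
            (copies[g] / total_copies) * weights[g] for g in groups_present
        ])
        count_cols[sid] = rng.multinomial(read_depth, probs / probs.sum())

        # --- lipids ---
        ip_frac = cfg.ip_fraction[cluster]
        ip_true = {c: 0.0 for c in ANALYTES}
        for g, quota in cfg.true_quota.items():
            pool = cells.get(g, 0.0) * quota
            for c, share in cfg.lipid_signature[g].items():
                ip_true[c] += pool * share
        total_true = {c: v / ip_frac for c, v in ip_true.items()}
        core_true = {c: total_true[c] - ip_true[c] for c in ANALYTES}

        sigma_h = cfg.noise_sigma
        sigma_nh = float(np.hypot(cfg.noise_sigma, cfg.matrix_effect_sigma))
        for c in ANALYTES:
            noise_area = _area_from_conc(cfg.noise_floor_ng_per_L, c, cfg, qc) / 5.0
            if total_true[c] > 0:
                area = _area_from_conc(total_true[c], c, cfg, qc) * float(np.exp(rng.normal(0, sigma_h)))
                peak_rows.append((sid, "hydrolyzed", c, "core", "M+NH4",
                                  area, noise_area, cfg.is_area, cfg.is_mass_ng, cfg.volume_L))
            if core_true[c] > 0:
                area = _area_from_conc(core_true[c], c, cfg, qc) * float(np.exp(rng.normal(0, sigma_nh)))
                peak_rows.append((sid, "non_hydrolyzed", c, "core", "M+NH4",
                                  area, noise_area, cfg.is_area, cfg.is_mass_ng, cfg.volume_L))
            if ip_true[c] > 0:
                if c == ARCHEOL:
                    splits = {"MH": 1.0}  # archeol IP occurs only as monohexose
                else:
                    splits = cfg.headgroup_split
                for cls in IPL_CLASSES:
                    if cls not in splits:
                        continue
                    area = (_area_from_conc(ip_true[c], c, cfg, qc) * splits[cls]
                            * float(np.exp(rng.normal(0, sigma_nh))))
                    peak_rows.append((sid, "non_hydrolyzed", c, cls, "M+NH4",
                                      area, noise_area, cfg.is_area, cfg.is_mass_ng, cfg.volume_L))

        ddpcr_rows.append((sid, total_copies))
        cells_rows[sid] = {g: cells.get(g, 0.0) for g in groups_present}
        ip_rows[sid] = ip_true
        total_rows[sid] = total_true

    count_table = pd.DataFrame(count_cols, index=aasv_ids)
    taxonomy = pd.Series(aasv_group, index=aasv_ids, name="group")
    taxonomy.index.name = "aasv_id"
    clusters = pd.Series(sample_cluster, index=sample_ids, name="cluster")
    chl = 0.05 + 0.25 * np.exp(-((np.asarray(sample_depth, float) - cfg.dcm_depth) / 25.0) ** 2)
    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "station": stations,
        "depth_m": sample_depth,
        "dcm_depth_m": cfg.dcm_depth,
        "cluster": sample_cluster,
        "chl_a_ug_per_L": np.round(chl, 4),
    })
    truth = SyntheticTruth(
        cells=pd.DataFrame(cells_rows).T.reindex(sample_ids),
        ip_conc=pd.DataFrame(ip_rows).T.reindex(sample_ids)[list(ANALYTES)],
        total_conc=pd.DataFrame(total_rows).T.reindex(sample_ids)[list(ANALYTES)],
        ip_total=pd.DataFrame(ip_rows).T.reindex(sample_ids).sum(axis=1).rename("ip_total"),
        quotas=dict(cfg.true_quota),
        clusters=clusters,
    )
    return SyntheticDataset(
        peak_table=pd.DataFrame(peak_rows, columns=PEAK_COLUMNS),
        count_table=count_table,
        taxonomy=taxonomy,
        ddpcr=pd.DataFrame(ddpcr_rows, columns=["sample_id", "copies_per_L"]),
        metadata=metadata,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the dataset in the dialects the quantification and community
    readers consume, plus the ground truth as JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": out / "peaks.csv",
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "ddpcr": out / "ddpcr.csv",
        "metadata": out / "metadata.csv",
        "truth": out / "truth.json",
    }
    ds.peak_table.to_csv(paths["peaks"], index=False, float_format="%.17g")
    ds.count_table.to_csv(paths["counts"], sep="\t", index_label="aasv_id")
    ds.taxonomy.reset_index().to_csv(paths["taxonomy"], sep="\t", index=False)
    ds.ddpcr.to_csv(paths["ddpcr"], index=False, float_format="%.17g")
    ds.metadata.to_csv(paths["metadata"], index=False)
    paths["truth"].write_text(ds.truth.to_json())
    return {k: str(v) for k, v in paths.items()}
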