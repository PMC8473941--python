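"""End-to-end orchestration: quantify -> abundance -> budget -> statistics.

Every stage is a pure function of its inputs and the run configuration;
re-running with an identical configuration reproduces identical outputs. A
provenance record (config hash, seed, package version) is written next to
the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .budget import BudgetParameters, BudgetReport, compute_budget
from .community import (
    CountTable,
    abundance_frame,
    abundance_profiles,
    alpha_diversity_frame,
    read_count_table,
    read_ddpcr,
)
from .compounds import ANALYTES, IPL_CLASSES
from .errors import ConfigError, GdgtBudgetError, StageError, UndefinedResultError
from .lipid_quant import (
    LipidProfile,
    QuantConfig,
    build_profiles,
    class_distribution_frame,
    profiles_to_frame,
    read_peak_table,
)
from .stats import bray_curtis_matrix, mantel, nmds
from .synthetic import SyntheticConfig, SyntheticDataset, generate, write_dataset


@dataclass
class RunConfig:
    """Single source of pipeline parameters.

    Either the four input paths are given, or ``simulate`` holds a
    :class:`SyntheticConfig` and the inputs are generated (and written to
    ``outdir/inputs``).
    """

    peaks: str | None = None
    counts: str | None = None
    taxonomy: str | None = None
    ddpcr: str | None = None
    outdir: str = "gdgtbudget_out"
    seed: int = 0
    n_perm: int = 999
    n_restarts: int = 20
    quant: QuantConfig = field(default_factory=QuantConfig)
    budget: BudgetParameters = field(default_factory=BudgetParameters)
    simulate: SyntheticConfig | None = None

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as e:
            raise ConfigError(f"cannot read config {path!r}: {e}") from e
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        try:
            if "quant" in kwargs:
                kwargs["quant"] = QuantConfig(**kwargs["quant"])
            if "budget" in kwargs:
                kwargs["budget"] = BudgetParameters(**kwargs["budget"])
            if "simulate" in kwargs and kwargs["simulate"] is not None:
                sim = SyntheticConfig(**kwargs["simulate"])
                sim.validate()
                kwargs["simulate"] = sim
        except TypeError as e:
            raise ConfigError(str(e)) from e
        cfg = cls(**kwargs)
        if not isinstance(cfg.seed, int):
            raise ConfigError("seed must be an integer")
        return cfg

    def validate_inputs(self) -> None:
        if self.simulate is not None:
            return
        required = {"peaks": self.peaks, "counts": self.counts,
                    "taxonomy": self.taxonomy, "ddpcr": self.ddpcr}
        missing = [k for k, v in required.items() if v is None]
        if missing:
            raise ConfigError(f"missing input paths (and no simulate config): {missing}")
        absent = [v for v in required.values() if not Path(v).exists()]
        if absent:
            raise ConfigError(f"input files do not exist: {absent}")

    def canonical_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o).__name__)
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()


def lipid_feature_matrix(profiles: list[LipidProfile]) -> pd.DataFrame:
    """Per-sample lipid composition vector for distance calculations.

    Concatenates the relative total-lipid composition (hydrolyzed fraction)
    with the per-head-group-class relative distributions, one block per
    class; each block sums to one where measured. Samples with no
    quantifiable lipid are dropped by the caller.
    """
    rows = {}
    for p in profiles:
        total = sum(p.total_conc.values())
        if total == 0:
            continue
        vec = {f"total:{c}": p.total_conc[c] / total for c in ANALYTES}
        for cls in IPL_CLASSES:
            dist = p.ipl_class_distribution.get(cls, {})
            for c in ANALYTES:
                vec[f"{cls}:{c}"] = dist.get(c, 0.0)
        rows[p.sample_id] = vec
    return pd.DataFrame(rows).T.fillna(0.0)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except GdgtBudgetError as e:
            raise StageError(name, str(e)) from e
    return wrap


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline and write the report bundle into ``outdir``."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # inputs
    if config.simulate is not None:
        ds: SyntheticDataset = _stage("simulate")(generate, config.simulate, config.seed)
        write_dataset(ds, outdir / "inputs")
        records = ds.peak_records()
        tbl = CountTable(counts=ds.count_table, taxonomy=ds.taxonomy)
        ddpcr = {str(r.sample_id): float(r.copies_per_L) for r in ds.ddpcr.itertuples(index=False)}
    else:
        records = _stage("read")(read_peak_table, config.peaks)
        tbl = _stage("read")(read_count_table, config.counts, config.taxonomy)
        ddpcr = _stage("read")(read_ddpcr, config.ddpcr)

    # quantify
    profiles = _stage("quantify")(build_profiles, records, config.quant)
    profiles_to_frame(profiles).to_csv(outdir / "lipid_profiles.csv", index=False)
    class_distribution_frame(profiles).to_csv(outdir / "ipl_distribution.csv", index=False)

    # abundance
    taxon = _stage("abundance")(abundance_profiles, tbl, ddpcr, config.budget.copy_number)
    abundance_frame(taxon).to_csv(outdir / "abundance.csv", index=False)
    alpha_diversity_frame(tbl).to_csv(outdir / "alpha_diversity.csv", index=False)

    # budget
    report: BudgetReport = _stage("budget")(compute_budget, profiles, taxon, config.budget)
    report.to_frame().to_csv(outdir / "budget.csv", index=False)
    (outdir / "budget.txt").write_text(report.to_text() + "\n")

    # statistics
    stats_out: dict = {"n_perm": config.n_perm, "n_restarts": config.n_restarts}
    community_rel = (tbl.counts / tbl.counts.sum(axis=0)).T  # samples x AASVs
    d_comm = _stage("stats")(bray_curtis_matrix, community_rel, False)
    ord_comm = _stage("stats")(nmds, d_comm, 2, config.n_restarts, 300, 1e-6, config.seed)
    lipid_feats = lipid_feature_matrix(profiles)
    pd.DataFrame(ord_comm.coordinates, index=d_comm.ids, columns=["NMDS1", "NMDS2"]) \
        .to_csv(outdir / "coordinates_community.csv", index_label="sample_id")
    stats_out["community"] = {"stress": ord_comm.stress, "converged": ord_comm.converged}

    if len(lipid_feats) >= 3:
        d_lip = _stage("stats")(bray_curtis_matrix, lipid_feats, False)
        ord_lip = _stage("stats")(nmds, d_lip, 2, config.n_restarts, 300, 1e-6, config.seed + 1)
        pd.DataFrame(ord_lip.coordinates, index=d_lip.ids, columns=["NMDS1", "NMDS2"]) \
            .to_csv(outdir / "coordinates_lipids.csv", index_label="sample_id")
        stats_out["lipids"] = {"stress": ord_lip.stress, "converged": ord_lip.converged}

        common = [s for s in d_comm.ids if s in set(d_lip.ids)]
        if len(common) >= 4:
            try:
                res = mantel(
                    d_comm.filter(common), d_lip.filter(common),
                    n_perm=config.n_perm, seed=config.seed + 2,
                )
                stats_out["mantel"] = {"r": res.r, "p": res.p, "n_perm": res.n_perm,
                                       "n_samples": len(common)}
            except UndefinedResultError as e:
                stats_out["mantel"] = {"error": str(e)}
        else:
            stats_out["mantel"] = {"error": "fewer than 4 shared samples"}
    else:
        stats_out["lipids"] = {"error": "fewer than 3 samples with quantifiable lipid"}

    (outdir / "stats.json").write_text(json.dumps(stats_out, indent=1, sort_keys=True))

    provenance = {
        "package": "gdgtbudget",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.canonical_hash(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))

    return {
        "profiles": profiles,
        "taxon_profiles": taxon,
        "budget": report,
        "stats": stats_out,
        "outdir": str(outdir),
    }
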