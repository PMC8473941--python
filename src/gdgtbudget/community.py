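"""Absolute archaeal taxon abundances and sequencing detection limits.

Amplicon sequence variant (AASV) counts give relative community structure;
droplet digital PCR (ddPCR) of the same SSU rRNA amplicon gives an absolute
total in copies/L. Multiplying the per-group read fraction by the ddPCR total
anchors each archaeal group on an absolute copies/L scale; copies convert to
cells with a per-cell rRNA operon copy number (1 for the planktonic
Thaumarchaeota and Thermoplasmatota considered here).

The sequencing detection limit of a sample is the relative abundance
corresponding to a single read, 100 / read_depth percent.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .errors import DataError

#: Archaeal group labels used throughout the package.
GROUPS = (
    "MGI-Thaumarchaeota",
    "MGII",
    "MGIII",
    "Halobacterota",
    "Nanoarchaeota",
    "Woesearchaeota",
    "other-archaea",
)

THAUMARCHAEOTA = "MGI-Thaumarchaeota"
THERMOPLASMATOTA_GROUPS = ("MGII", "MGIII")


@dataclass
class CountTable:
    """AASV count matrix (rows = AASVs, columns = samples) plus a group label
    per AASV."""

    counts: pd.DataFrame
    taxonomy: pd.Series  # aasv_id -> group label

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise DataError("AASV counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise DataError("AASV counts must be non-negative")
        missing = set(self.counts.index) - set(self.taxonomy.index)
        if missing:
            raise DataError(f"AASVs without a taxonomy label: {sorted(missing)[:5]}")
        bad = set(self.taxonomy.loc[list(self.counts.index)]) - set(GROUPS)
        if bad:
            raise DataError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_counts(self) -> pd.DataFrame:
        """Counts summed per group (rows = groups incl. zero rows, columns = samples)."""
        g = self.counts.groupby(self.taxonomy.loc[list(self.counts.index)].to_numpy()).sum()
        return g.reindex(list(GROUPS), fill_value=0)

    def read_depth(self, sample_id: str) -> int:
        return int(self.counts[sample_id].sum())


def absolute_abundance(tbl: CountTable, total_copies_per_L: float, sample_id: str) -> dict[str, float]:
    """Per-group absolute abundance in SSU rRNA copies/L.

    copies(group) = ddPCR total x (group reads / total reads). Conserves the
    ddPCR total across groups.
    """
    if sample_id not in tbl.counts.columns:
        raise DataError(f"sample {sample_id!r} not in count table")
    if total_copies_per_L < 0:
        raise DataError("total_copies_per_L must be >= 0")
    col = tbl.group_counts()[sample_id]
    total = col.sum()
    if total == 0:
        raise DataError(f"no reads for sample {sample_id!r}")
    return {g: total_copies_per_L * int(n) / int(total) for g, n in col.items()}


def copies_to_cells(copies_per_L: float, copy_number: float = 1.0) -> float:
    """Convert gene copies/L to cells/L with a per-cell rRNA copy number."""
    if not copy_number > 0:
        raise DataError("copy_number must be > 0")
    if copies_per_L < 0:
        raise DataError("copies_per_L must be >= 0")
    return copies_per_L / copy_number


def detection_limit(read_depth: int) -> float:
    """Relative abundance of a single read, in percent (100 / read_depth)."""
    if read_depth < 1:
        raise DataError("read_depth must be >= 1")
    return 100.0 / read_depth


def shannon(counts: Sequence[int]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) over nonzero taxa."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise DataError("counts must be non-negative")
    if arr.sum() == 0:
        raise DataError("all-zero count vector")
    return float(entropy(arr))


def richness(counts: Sequence[int]) -> int:
    """Observed richness: number of taxa with at least one read."""
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise DataError("counts must be non-negative")
    return int(np.count_nonzero(arr))


def rarefaction_curve(
    counts: Sequence[int],
    depths: Sequence[int],
    reps: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Mean observed richness over random subsamples without replacement.

    Subsampling uses exact multivariate hypergeometric draws; at full depth
    the curve equals the observed richness in every replicate.
    """
    arr = np.asarray(counts, dtype=np.int64)
    if (arr < 0).any():
        raise DataError("counts must be non-negative")
    total = int(arr.sum())
    if reps < 1:
        raise DataError("reps must be >= 1")
    if any(d > total for d in depths):
        raise DataError("subsampling depth exceeds total reads")
    if any(d < 0 for d in depths):
        raise DataError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    means = []
    for d in depths:
        hits = [np.count_nonzero(rng.multivariate_hypergeometric(arr, d)) for _ in range(reps)]
        means.append(float(np.mean(hits)))
    return np.asarray(means)


@dataclass
class TaxonAbundanceProfile:
    """Per-sample absolute abundances anchored on the ddPCR total."""

    sample_id: str
    copies_per_L: dict[str, float]
    cells_per_L: dict[str, float]
    read_depth: int
    detection_limit_percent: float

    @property
    def total_copies_per_L(self) -> float:
        return sum(self.copies_per_L.values())


def abundance_profiles(
    tbl: CountTable,
    ddpcr: Mapping[str, float],
    copy_number: float = 1.0,
) -> list[TaxonAbundanceProfile]:
    """Build per-sample absolute abundance profiles for samples present in
    both the count table and the ddPCR measurements."""
    out = []
    for sid in tbl.sample_ids:
        if sid not in ddpcr:
            raise DataError(f"sample {sid!r} missing from ddPCR table")
        copies = absolute_abundance(tbl, float(ddpcr[sid]), sid)
        cells = {g: copies_to_cells(v, copy_number) for g, v in copies.items()}
        depth = tbl.read_depth(sid)
        out.append(
            TaxonAbundanceProfile(
                sample_id=sid,
                copies_per_L=copies,
                cells_per_L=cells,
                read_depth=depth,
                detection_limit_percent=detection_limit(depth),
            )
        )
    return out


def abundance_frame(profiles: Sequence[TaxonAbundanceProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for g in GROUPS:
            rows.append({
                "sample_id": p.sample_id,
                "group": g,
                "copies_per_L": p.copies_per_L.get(g, 0.0),
                "cells_per_L": p.cells_per_L.get(g, 0.0),
                "read_depth": p.read_depth,
                "detection_limit_percent": p.detection_limit_percent,
            })
    return pd.DataFrame(rows)


def alpha_diversity_frame(tbl: CountTable) -> pd.DataFrame:
    """Per-sample read depth, richness and Shannon index."""
    rows = []
    for sid in tbl.sample_ids:
        col = tbl.counts[sid].to_numpy()
        rows.append({
            "sample_id": sid,
            "read_depth": int(col.sum()),
            "richness": richness(col),
            "shannon": shannon(col) if col.sum() > 0 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular IO

def read_count_table(counts_path: str, taxonomy_path: str) -> CountTable:
    """Read an AASV count TSV (rows = AASVs, columns = samples) and a
    two-column taxonomy TSV (aasv_id, group)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    tax = pd.read_csv(taxonomy_path, sep="\t")
    if tax.shape[1] < 2:
        raise DataError("taxonomy table needs columns (aasv_id, group)")
    taxonomy = tax.set_index(tax.columns[0])[tax.columns[1]]
    return CountTable(counts=counts, taxonomy=taxonomy)


def read_ddpcr(path: str) -> dict[str, float]:
    """Read a two-column CSV (sample_id, copies_per_L)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataError("ddPCR table needs columns (sample_id, copies_per_L)")
    return {str(r[0]): float(r[1]) for r in df.itertuples(index=False)}
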