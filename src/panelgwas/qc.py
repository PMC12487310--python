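"""Marker QC: per-site statistics and the three-stage filter cascade.

Markers are filtered sequentially on call rate (fraction of accessions with a
genotype, >= 0.90 by default), heterozygosity among called genotypes (<= 0.10;
high apparent heterozygosity in a pooled inbred sample flags reads collapsed
from several homoeologous loci), and minor allele frequency (> 0.05 strictly).
Statistics are computed on called genotypes only.  Filtering precedes
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, MarkerRecord
from .panel_design import panel_funnel_report


@dataclass(frozen=True)
class FilterParams:
    """Cascade thresholds; call-rate and het bounds inclusive, MAF strict."""

    min_call_rate: float = 0.90
    max_het_rate: float = 0.10
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "max_het_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def site_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate, het rate and MAF.

    ``call_rate`` = called/total accessions; ``het_rate`` = heterozygotes /
    called; ``maf`` = min(p, 1-p) with p the alt-allele frequency among
    called genotypes.  Markers with zero calls get call_rate 0 and NaN
    het/maf.
    """
    if gm.n_accessions < 1:
        raise ValueError("need at least one accession")
    calls = gm.calls
    called = (calls != MISSING).sum(axis=1).astype(float)
    n_het = (calls == 1).sum(axis=1)
    n_alt_hom = (calls == 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        call_rate = called / gm.n_accessions
        het = np.where(called > 0, n_het / called, np.nan)
        p = np.where(called > 0, (2 * n_alt_hom + n_het) / (2 * called), np.nan)
    maf = np.minimum(p, 1 - p)
    return pd.DataFrame(
        {
            "marker_id": gm.marker_ids,
            "call_rate": call_rate,
            "het_rate": het,
            "maf": maf,
        }
    )


def apply_filter_cascade(
    gm: GenotypeMatrix,
    markers: Sequence[MarkerRecord] | None = None,
    params: FilterParams = FilterParams(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply call-rate -> het -> MAF stages; return survivors and the funnel.

    Marker order is preserved.  The funnel table reports survivors after each
    stage overall and per selection category (all markers fall in one
    category ``G`` when no metadata are given).
    """
    stats = site_stats(gm)
    pass_call = stats["call_rate"].to_numpy() >= params.min_call_rate
    het = stats["het_rate"].to_numpy()
    maf = stats["maf"].to_numpy()
    pass_het = np.nan_to_num(het, nan=1.0) <= params.max_het_rate
    pass_maf = np.nan_to_num(maf, nan=0.0) > params.min_maf
    keep = pass_call & pass_het & pass_maf
    if markers is None:
        markers = [
            MarkerRecord(id=mid, chrom="Un", pos=i + 1)
            for i, mid in enumerate(gm.marker_ids)
        ]
    flags = pd.DataFrame(
        {"call_rate": pass_call, "het": pass_het, "maf": pass_maf},
        index=gm.marker_ids,
    )
    funnel = panel_funnel_report(markers, flags, stages=("call_rate", "het", "maf"))
    return gm.subset_markers(keep), funnel
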