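"""Missingness-based detection of alien translocations and large deletions.

Enrichment probes designed against the wheat reference fail to hybridize on
chromatin replaced by alien chromatin (e.g. the rye 1RS arm replacing wheat
1BS in the 1RS.1BL translocation), so carriers show a contiguous block of
no-call genotypes on the affected arm.  The scan profiles per-marker
missingness along chromosomes, counts missing calls per accession inside a
window, splits the count distribution at its largest gap(s) into carrier /
intermediate / non-carrier classes, and measures concordance against
external validation labels (e.g. a diagnostic PCR marker).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, MarkerRecord


def missingness_profile(
    gm: GenotypeMatrix, markers: Sequence[MarkerRecord]
) -> pd.DataFrame:
    """Per-marker fraction of accessions missing, sorted by (chrom, pos)."""
    by_id = {m.id: m for m in markers}
    frac = (gm.calls == MISSING).mean(axis=1)
    df = pd.DataFrame(
        {
            "marker_id": gm.marker_ids,
            "chrom": [by_id[mid].chrom for mid in gm.marker_ids],
            "pos": [by_id[mid].pos for mid in gm.marker_ids],
            "missing_fraction": frac,
        }
    )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _window_rows(
    gm: GenotypeMatrix,
    markers: Sequence[MarkerRecord],
    window: tuple[str, object, object],
) -> np.ndarray:
    """Row indices of markers inside an inclusive window given by marker ids
    or base-pair bounds on one chromosome."""
    chrom, lo, hi = window
    by_id = {m.id: m for m in markers}
    if isinstance(lo, str):
        lo = by_id[lo].pos
    if isinstance(hi, str):
        hi = by_id[hi].pos
    lo, hi = int(lo), int(hi)
    if hi < lo:
        lo, hi = hi, lo
    rows = [
        i
        for i, mid in enumerate(gm.marker_ids)
        if by_id[mid].chrom == chrom and lo <= by_id[mid].pos <= hi
    ]
    return np.array(rows, dtype=int)


def auto_thresholds(
    counts: Sequence[int] | np.ndarray,
    gap_ratio: float = 0.5,
    min_gap: int = 2,
) -> tuple[int, int]:
    """Thresholds from the largest gap(s) in the sorted count distribution.

    The largest gap splits non-carriers from carriers; when the second
    largest gap is at least ``gap_ratio`` of the largest, the region between
    the two gaps becomes the intermediate class.  Returns ``(t_low, t_high)``
    such that counts <= t_low are non-carriers and counts >= t_high are
    carriers.  A unimodal distribution (largest gap < ``min_gap``) returns
    ``(max, max)`` so everyone classifies as non-carrier.
    """
    counts = np.asarray(counts)
    if counts.size < 2:
        raise ValueError("need at least 2 accessions")
    vals = np.unique(counts)
    if vals.size == 1:
        return int(vals[0]), int(vals[0])
    gaps = np.diff(vals)
    order = np.argsort(-gaps, kind="stable")
    g1 = order[0]
    if gaps[g1] < min_gap:
        return int(vals[-1]), int(vals[-1])
    if gaps.size > 1 and gaps[order[1]] >= gap_ratio * gaps[g1]:
        g2 = order[1]
        lo_gap, hi_gap = sorted((g1, g2))
        return int(vals[lo_gap]), int(vals[hi_gap + 1])
    return int(vals[g1]), int(vals[g1 + 1])


@dataclass(frozen=True)
class CarrierCall:
    accession_id: str
    n_missing: int
    klass: str  # carrier / non_carrier / intermediate


def classify_carriers(
    gm: GenotypeMatrix,
    markers: Sequence[MarkerRecord],
    window: tuple[str, object, object],
    thresholds: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Classify accessions by missing-call count inside the window.

    Counts <= t_low are non-carriers, counts >= t_high carriers, anything
    strictly between is intermediate.  When ``thresholds`` is None they are
    derived with :func:`auto_thresholds`.
    """
    rows = _window_rows(gm, markers, window)
    if rows.size == 0:
        raise ValueError("window contains no markers")
    counts = (gm.calls[rows] == MISSING).sum(axis=0)
    if thresholds is None:
        thresholds = auto_thresholds(counts)
    t_low, t_high = thresholds
    if t_low > t_high:
        raise ValueError("t_low must be <= t_high")
    klass = np.where(
        counts <= t_low, "non_carrier", np.where(counts >= t_high, "carrier", "intermediate")
    )
    return pd.DataFrame(
        {
            "accession_id": gm.accession_ids,
            "n_missing": counts,
            "class": klass,
        }
    )


def concordance(
    calls: pd.DataFrame, labels: Mapping[str, bool] | pd.Series
) -> tuple[float, pd.DataFrame, int]:
    """Agreement of carrier calls with external validation labels.

    ``labels`` maps accession id to True (validated carrier) / False.
    Intermediate calls are excluded from the 2x2 table and reported as a
    separate count.  Returns (agreement fraction, confusion table,
    n_intermediate_overlapping).
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    sub = calls[calls["accession_id"].isin(labels.keys())]
    if sub.empty:
        raise ValueError("no overlap between carrier calls and validation labels")
    inter = int((sub["class"] == "intermediate").sum())
    sub = sub[sub["class"] != "intermediate"]
    if sub.empty:
        raise ValueError("no non-intermediate overlap with validation labels")
    pred = (sub["class"] == "carrier").to_numpy()
    truth = np.array([bool(labels[a]) for a in sub["accession_id"]])
    table = pd.DataFrame(
        {
            "validated_carrier": [int((pred & truth).sum()), int((~pred & truth).sum())],
            "validated_non_carrier": [
                int((pred & ~truth).sum()),
                int((~pred & ~truth).sum()),
            ],
        },
        index=["called_carrier", "called_non_carrier"],
    )
    agreement = float((pred == truth).mean())
    return agreement, table, inter


def scan_genome(
    gm: GenotypeMatrix,
    markers: Sequence[MarkerRecord],
    window_markers: int = 20,
    min_gap: int = 2,
) -> pd.DataFrame:
    """Sliding-window whole-genome scan for carrier-like missingness blocks.

    For each window of ``window_markers`` consecutive markers per chromosome
    (``Un`` excluded), applies the automatic gap split and reports windows
    where a carrier class separates.  Returns one row per chromosome with
    the strongest window (largest count gap) and its carrier count.
    """
    by_id = {m.id: m for m in markers}
    recs = []
    for chrom in sorted({m.chrom for m in markers if m.chrom != "Un"}):
        rows = [
            i for i, mid in enumerate(gm.marker_ids) if by_id[mid].chrom == chrom
        ]
        rows.sort(key=lambda i: by_id[gm.marker_ids[i]].pos)
        best = None
        for start in range(0, max(len(rows) - window_markers + 1, 1)):
            idx = np.array(rows[start : start + window_markers])
            if idx.size == 0:
                continue
            counts = (gm.calls[idx] == MISSING).sum(axis=0)
            vals = np.unique(counts)
            gap = int(np.diff(vals).max()) if vals.size > 1 else 0
            if best is None or gap > best[0]:
                t_low, t_high = auto_thresholds(counts, min_gap=min_gap)
                n_car = int((counts >= t_high).sum()) if t_high > t_low else 0
                best = (gap, by_id[gm.marker_ids[idx[0]]].pos,
                        by_id[gm.marker_ids[idx[-1]]].pos, n_car)
        if best is not None:
            recs.append(
                {
                    "chrom": chrom,
                    "max_gap": best[0],
                    "window_start": best[1],
                    "window_end": best[2],
                    "n_carriers": best[3],
                }
            )
    return pd.DataFrame(recs)
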