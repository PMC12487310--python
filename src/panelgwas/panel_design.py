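"""Candidate-SNP targetability screening.

A SNP can only be targeted by an enrichment probe when the sequence around it
is unique in the genome (allohexaploid wheat carries near-identical
homoeologous copies on the A, B and D subgenomes) and the probe GC content
falls in a workable hybridization band.  This module computes flank GC
content, exact-match uniqueness of the SNP-centered fragment against a
reference, probe feasibility, and the per-category survival funnel across
sequential filtering stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CATEGORIES, MarkerRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def flank_gc_content(seq: str) -> float:
    """GC fraction of a nucleotide string; N bases leave the denominator.

    Returns NaN for an all-N (or empty-after-N) sequence.
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    denom = sum(s.count(b) for b in "ACGT")
    if denom == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / denom


def count_exact_matches(fragment: str, reference: Mapping[str, str] | Iterable[str]) -> int:
    """Occurrences of ``fragment`` (or its reverse complement) in the reference.

    Overlapping occurrences count; a position where the forward and
    reverse-complement matches coincide (palindromic fragment) counts once.
    """
    if not fragment:
        raise ValueError("empty fragment")
    frag = fragment.upper()
    rc = reverse_complement(frag)
    seqs = reference.values() if isinstance(reference, Mapping) else reference
    total = 0
    for seq in seqs:
        s = seq.upper()
        positions = set()
        for query in {frag, rc}:  # a set: palindromes scanned once
            start = s.find(query)
            while start != -1:
                positions.add(start)
                start = s.find(query, start + 1)
        total += len(positions)
    return total


@dataclass(frozen=True)
class FlankReport:
    marker_id: str
    gc_fraction: float
    n_exact_hits: int

    @property
    def unique(self) -> bool:
        return self.n_exact_hits == 1


def flank_reports(
    markers: Sequence[MarkerRecord], reference: Mapping[str, str]
) -> pd.DataFrame:
    """Per-marker flank GC and exact-hit counts against the reference."""
    rows = []
    for m in markers:
        if m.flank is None:
            raise ValueError(f"marker {m.id} has no flank sequence")
        hits = count_exact_matches(m.flank, reference)
        rows.append(
            {
                "marker_id": m.id,
                "gc_fraction": flank_gc_content(m.flank),
                "n_exact_hits": hits,
                "unique": hits == 1,
            }
        )
    return pd.DataFrame(rows)


def probe_feasibility(
    flank: FlankReport | Mapping,
    probes: pd.DataFrame | Mapping | Sequence[Mapping],
    gc_min: float = 0.30,
    gc_max: float = 0.70,
) -> tuple[bool, str]:
    """Decide whether at least one probe can target the SNP.

    Rejection reasons: ``multilocus`` when the flank matches more than one
    genomic locus (no specific probe exists), ``gc`` when every candidate
    probe's GC content lies outside [gc_min, gc_max].  Returns
    ``(feasible, reason)`` with reason ``""`` when feasible.
    """
    if not 0.0 <= gc_min < gc_max <= 1.0:
        raise ValueError("require 0 <= gc_min < gc_max <= 1")
    n_hits = flank.n_exact_hits if isinstance(flank, FlankReport) else flank["n_exact_hits"]
    if n_hits > 1:
        return False, "multilocus"
    if isinstance(probes, Mapping):
        probes = [probes]
    if isinstance(probes, pd.DataFrame):
        gcs = probes["gc_fraction"].tolist()
    else:
        gcs = [p["gc_fraction"] for p in probes]
    if any(gc_min <= g <= gc_max for g in gcs):
        return True, ""
    return False, "gc"


_FUNNEL_STAGES = ("initial", "probe_design", "call_rate", "het", "maf")


def panel_funnel_report(
    markers: Sequence[MarkerRecord],
    stage_flags: pd.DataFrame,
    stages: Sequence[str] = _FUNNEL_STAGES[1:],
) -> pd.DataFrame:
    """Per-category survival counts across sequential filtering stages.

    ``stage_flags`` is indexed by marker id with one boolean column per stage;
    survival at stage *k* requires passing stages 1..k (sequential cascade),
    so counts are non-increasing left-to-right.  A ``pct_of_initial`` column
    reports the final survivors as a percentage of the initial count.
    """
    cats = {m.id: m.category for m in markers}
    unknown = set(cats.values()) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    ids = [m.id for m in markers]
    missing = [i for i in ids if i not in stage_flags.index]
    if missing:
        raise ValueError(f"stage flags missing for markers {missing[:5]}")
    flags = stage_flags.loc[ids, list(stages)].to_numpy(dtype=bool)
    surviving = np.ones(len(ids), dtype=bool)
    cat_arr = np.array([cats[i] for i in ids])
    table = {}
    order = [c for c in CATEGORIES if c in set(cat_arr)] or []
    table["initial"] = {c: int((cat_arr == c).sum()) for c in order}
    for j, stage in enumerate(stages):
        surviving &= flags[:, j]
        table[stage] = {c: int(((cat_arr == c) & surviving).sum()) for c in order}
    df = pd.DataFrame(table).T
    df.loc["initial", "total"] = sum(df.loc["initial", order]) if order else 0
    for stage in stages:
        df.loc[stage, "total"] = sum(df.loc[stage, order]) if order else 0
    df = df.astype(int)
    out = df.T
    last = stages[-1] if len(stages) else "initial"
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_of_initial"] = np.where(
            out["initial"] > 0, 100.0 * out[last] / out["initial"], 0.0
        )
    return out
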