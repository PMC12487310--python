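"""Synthetic genotype/phenotype/reference generator.

Emulates the statistical structure of a targeted-genotyping panel applied to
an inbred winter-wheat collection: ~3.5 K polymorphic biallelic markers over
21 nuclear chromosomes plus an "Un" bin of unplaced contigs, with marker
density increasing toward the distal chromosome ends; 200 accessions drawn
from two admixed subpopulations under a Balding-Nichols divergence model;
low residual heterozygosity (pooled-sample heterogeneity); uniform background
missingness plus a contiguous high-missingness block on one chromosome arm in
a carrier subset (the signature of an alien translocation such as 1RS.1BL);
and multi-year quantitative traits with one to three major-effect loci on a
polygenic background, plus one binary trait.

All randomness flows from one root seed through named child streams
(reference, population, translocation, traits), so stages can be re-run
independently and outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, CATEGORIES, GenotypeMatrix, MarkerRecord

_STREAMS = ("reference", "population", "translocation", "traits")


@dataclass(frozen=True)
class TranslocationSpec:
    """A contiguous high-missingness block on one chromosome arm."""

    chrom: str = "1B"
    start_bp: int = 1
    end_bp: int = 155_000_000  # short-arm interval
    n_carriers: int = 39
    carrier_missing_rate: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_missing_rate <= 1.0:
            raise ValueError("carrier_missing_rate must be in [0, 1]")
        if self.end_bp < self.start_bp:
            raise ValueError("translocation interval is empty")


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: major loci + polygenic background + year effects.

    ``causal`` maps marker index (into the simulated marker list) to an
    effect size expressed in phenotypic standard deviations per alt-allele
    dosage unit.  ``heritability`` is the broad-sense fraction of phenotypic
    variance (major loci + polygenic) within a year.
    """

    name: str
    causal: dict[int, float] = field(default_factory=dict)
    heritability: float = 0.5
    n_years: int = 3
    year_effects: tuple[float, ...] | None = None
    binary: bool = False
    binary_prevalence: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must be in (0, 1]")
        if self.year_effects is not None and len(self.year_effects) != self.n_years:
            raise ValueError("year_effects length must equal n_years")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic panel.

    Defaults mirror the emulated study: 200 accessions from 2 admixed
    subpopulations, ~3.5 K markers on 21+1 chromosomes with distal
    clustering, low residual heterozygosity, 2% background missingness and a
    39-carrier translocation block on the 1B short arm.
    """

    n_accessions: int = 200
    n_markers: int = 3456
    n_chromosomes: int = 21
    chrom_length_bp: int = 600_000_000
    K_true: int = 2
    divergence: float = 0.15  # Balding-Nichols Fst-like parameter
    admixture_fraction: float = 0.2
    het_rate: float = 0.01
    base_missing_rate: float = 0.02
    maf_floor: float = 0.05
    translocation: TranslocationSpec | None = TranslocationSpec()
    traits: tuple[TraitSpec, ...] = ()
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.004, "B": 0.087, "C": 0.037, "D": 0.66, "G": 0.212}
    )
    distal_clustering: bool = True
    un_fraction: float = 0.01  # markers assigned to the unplaced "Un" bin
    # LD block structure (free parameter; 1 = independent markers)
    ld_block_size: int = 1
    ld_switch_prob: float = 0.05  # per-marker chance to break out of a block pattern
    block_gap_bp: int = 20_000
    # toy reference (panel-design fixtures)
    ref_chrom_length_bp: int = 20_000
    flank_length: int = 101
    duplication_fraction: float = 0.0
    probe_length: int = 40
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "admixture_fraction", "het_rate", "base_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.translocation is not None and self.translocation.n_carriers > self.n_accessions:
            raise ValueError("n_carriers exceeds n_accessions")
        if self.flank_length % 2 != 1:
            raise ValueError("flank_length must be odd")

    def stream(self, name: str) -> np.random.Generator:
        """Named child RNG stream derived from the root seed."""
        idx = _STREAMS.index(name)
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed).spawn(len(_STREAMS))[idx]
        )


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic data."""

    subpop_labels: np.ndarray  # (n_accessions,) int, argmax ancestry
    ancestry: np.ndarray  # (n_accessions, K_true) fractions summing to 1
    carrier_ids: list[str] = field(default_factory=list)
    causal_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    genetic_values: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self, accession_ids: Sequence[str]) -> pd.DataFrame:
        df = pd.DataFrame({"accession_id": list(accession_ids)})
        df["subpop"] = self.subpop_labels
        for k in range(self.ancestry.shape[1]):
            df[f"q{k + 1}"] = self.ancestry[:, k]
        df["carrier"] = df["accession_id"].isin(self.carrier_ids).astype(int)
        return df


# ---------------------------------------------------------------------------
# marker maps

def _marker_positions(cfg: SimulationConfig, rng: np.random.Generator) -> list[MarkerRecord]:
    """Draw marker placements; density is U-shaped along each chromosome when
    distal clustering is on (mimicking gene-rich distal arms)."""
    chrom_names = sorted(
        [f"{i}{sub}" for sub in ("A", "B", "D") for i in range(1, 8)][: cfg.n_chromosomes]
    )
    n_un = int(round(cfg.un_fraction * cfg.n_markers)) if chrom_names else 0
    n_placed = cfg.n_markers - n_un
    chrom_of = rng.integers(0, len(chrom_names), size=n_placed)
    cats = list(cfg.category_proportions)
    probs = np.array([cfg.category_proportions[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    categories = rng.choice(cats, size=cfg.n_markers, p=probs)
    bases = np.array(list("ACGT"))
    markers: list[MarkerRecord] = []
    n_blocks_gap = max(cfg.ld_block_size, 1)
    counter = 0
    for ci, cname in enumerate(chrom_names):
        n_here = int((chrom_of == ci).sum())
        if n_here == 0:
            continue
        n_anchor = max(1, n_here // n_blocks_gap)
        if cfg.distal_clustering:
            u = rng.beta(0.45, 0.45, size=n_anchor)
        else:
            u = rng.random(size=n_anchor)
        anchors = np.sort((u * (cfg.chrom_length_bp - 1)).astype(np.int64) + 1)
        pos = []
        for a in anchors:
            for j in range(n_blocks_gap):
                pos.append(min(int(a) + j * cfg.block_gap_bp, cfg.chrom_length_bp))
        pos = sorted(set(pos))[:n_here]
        while len(pos) < n_here:  # top up after de-duplication
            extra = int(rng.integers(1, cfg.chrom_length_bp + 1))
            if extra not in pos:
                pos.append(extra)
        for p in sorted(pos):
            ref, alt = rng.choice(4, size=2, replace=False)
            markers.append(
                MarkerRecord(
                    id=f"IAB{counter + 1:05d}",
                    chrom=cname,
                    pos=int(p),
                    category=str(categories[counter]),
                    ref_allele=str(bases[ref]),
                    alt_allele=str(bases[alt]),
                )
            )
            counter += 1
    for _ in range(cfg.n_markers - counter):
        ref, alt = rng.choice(4, size=2, replace=False)
        markers.append(
            MarkerRecord(
                id=f"IAB{counter + 1:05d}",
                chrom="Un",
                pos=int(rng.integers(1, cfg.chrom_length_bp + 1)),
                category=str(categories[counter]),
                ref_allele=str(bases[ref]),
                alt_allele=str(bases[alt]),
            )
        )
        counter += 1
    return markers


# ---------------------------------------------------------------------------
# population

def simulate_population(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, list[MarkerRecord], TruthSet]:
    """Draw genotypes under a correlated-allele-frequency admixture model.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each subpopulation's
    frequencies are Balding-Nichols Beta draws around the ancestral values
    with the configured divergence; each accession's genotype at a marker is
    Binomial(2, q_i . p_m).  Heterozygote calls are then thinned by
    resampling so the realized het rate matches ``het_rate``, and uniform
    background missingness is applied.  Optional block-LD structure copies a
    latent block genotype along runs of ``ld_block_size`` consecutive markers.
    """
    rng = cfg.stream("population")
    markers = _marker_positions(cfg, cfg.stream("reference"))
    n, M, K = cfg.n_accessions, cfg.n_markers, cfg.K_true

    p_anc = rng.uniform(cfg.maf_floor, 1 - cfg.maf_floor, size=M)
    if cfg.divergence > 0 and K > 1:
        F = cfg.divergence
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = np.stack([rng.beta(a, b) for _ in range(K)], axis=1)  # (M, K)
    else:
        p_sub = np.repeat(p_anc[:, None], K, axis=1)
    p_sub = np.clip(p_sub, 0.01, 0.99)

    labels = rng.integers(0, K, size=n)
    ancestry = np.zeros((n, K))
    ancestry[np.arange(n), labels] = 1.0
    admixed = rng.random(n) < cfg.admixture_fraction
    ancestry[admixed] = rng.dirichlet(np.ones(K), size=int(admixed.sum()))
    labels = ancestry.argmax(axis=1)

    freq = ancestry @ p_sub.T  # (n, M) accession-specific alt frequency
    if cfg.ld_block_size > 1:
        calls = np.empty((M, n), dtype=np.int8)
        # latent block genotype per accession, refreshed at block starts or
        # with ld_switch_prob per marker; gives strong local LD
        block = rng.binomial(2, freq[:, 0])
        order = np.arange(M)
        for m in order:
            refresh = (m % cfg.ld_block_size == 0) | (
                rng.random(n) < cfg.ld_switch_prob
            )
            new = rng.binomial(2, freq[:, m])
            block = np.where(refresh, new, block)
            calls[m] = block
    else:
        calls = rng.binomial(2, freq.T).astype(np.int8)  # (M, n)

    # thin heterozygotes toward the configured residual rate
    het = calls == 1
    cur = het.mean()
    if cur > cfg.het_rate > 0:
        resample = het & (rng.random(calls.shape) > cfg.het_rate / cur)
        calls[resample] = 2 * rng.binomial(1, freq.T[resample]).astype(np.int8)
    elif cfg.het_rate == 0:
        calls[het] = 2 * rng.binomial(1, freq.T[het]).astype(np.int8)

    if cfg.base_missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.base_missing_rate] = MISSING

    gm = GenotypeMatrix([m.id for m in markers],
                        [f"ACC{i + 1:03d}" for i in range(n)], calls)
    truth = TruthSet(subpop_labels=labels, ancestry=ancestry)
    return gm, markers, truth


def inject_translocation_missingness(
    gm: GenotypeMatrix,
    markers: Sequence[MarkerRecord],
    spec: TranslocationSpec,
    truth: TruthSet,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Set carrier genotypes inside the arm interval to MISSING.

    Carriers are chosen uniformly at random; each in-window call is masked
    independently with ``carrier_missing_rate``.  Non-carriers are unchanged.
    """
    import warnings

    if rng is None:
        rng = np.random.default_rng(0)
    in_window = np.array(
        [m.chrom == spec.chrom and spec.start_bp <= m.pos <= spec.end_bp for m in markers]
    )
    if not in_window.any():
        warnings.warn("translocation interval contains no markers; no-op", stacklevel=2)
        return gm
    out = gm.copy()
    if spec.n_carriers == 0:
        truth.carrier_ids = []
        return out
    carriers = rng.choice(gm.n_accessions, size=spec.n_carriers, replace=False)
    rows = np.flatnonzero(in_window)
    mask = rng.random((rows.size, carriers.size)) < spec.carrier_missing_rate
    sub = out.calls[np.ix_(rows, carriers)]
    sub[mask] = MISSING
    out.calls[np.ix_(rows, carriers)] = sub
    truth.carrier_ids = [gm.accession_ids[i] for i in sorted(carriers)]
    return out


# ---------------------------------------------------------------------------
# traits

def simulate_traits(
    gm: GenotypeMatrix,
    markers: Sequence[MarkerRecord],
    truth: TruthSet,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Simulate multi-year traits: y = sum(effect . dosage) + polygenic + year + noise.

    The polygenic term is multivariate normal with covariance proportional to
    the centered-IBS kinship of the genotype matrix (missing calls mean-filled
    for kinship only); noise is scaled so the within-year heritability matches
    the trait spec.  Binary traits threshold the liability at the configured
    prevalence.
    """
    from .popstructure import centered_ibs_kinship

    rng = cfg.stream("traits")
    n = gm.n_accessions
    X = gm.dosage()
    mu = np.nanmean(X, axis=1, keepdims=True)
    Xf = np.where(np.isnan(X), mu, X)
    filled = GenotypeMatrix(
        list(gm.marker_ids), list(gm.accession_ids),
        np.clip(np.rint(Xf), 0, 2).astype(np.int8),
    )
    K = centered_ibs_kinship(filled)
    # scale kinship to unit mean diagonal so polygenic variance is interpretable
    K = K / max(np.mean(np.diag(K)), 1e-12)
    L = np.linalg.cholesky(K + 1e-6 * np.eye(n))

    records = []
    for spec in cfg.traits:
        major = np.zeros(n)
        eff_by_id: dict[str, float] = {}
        for idx, beta in spec.causal.items():
            if np.isnan(X[idx]).all():
                raise ValueError(
                    f"causal marker {gm.marker_ids[idx]} is entirely missing"
                )
            major += beta * Xf[idx]
            eff_by_id[gm.marker_ids[idx]] = beta
        var_major = float(np.var(major))
        var_poly = max(spec.heritability - var_major, 0.0)
        var_noise = max(1.0 - spec.heritability, 1e-12)
        poly = np.sqrt(var_poly) * (L @ rng.standard_normal(n))
        g = major + poly
        truth.causal_effects[spec.name] = eff_by_id
        truth.genetic_values[spec.name] = g
        years = (
            np.asarray(spec.year_effects, dtype=float)
            if spec.year_effects is not None
            else rng.normal(0.0, 0.5, size=spec.n_years)
        )
        for yi in range(spec.n_years):
            y = g + years[yi] + np.sqrt(var_noise) * rng.standard_normal(n)
            if spec.binary:
                cut = np.quantile(y, 1 - spec.binary_prevalence)
                y = (y > cut).astype(float)
            for acc, val in zip(gm.accession_ids, y):
                records.append(
                    {
                        "accession_id": acc,
                        "trait": spec.name,
                        "year": 2018 + yi,
                        "value": float(val),
                    }
                )
    return pd.DataFrame(records, columns=["accession_id", "trait", "year", "value"])


# ---------------------------------------------------------------------------
# toy reference + probes

def simulate_reference(
    cfg: SimulationConfig, markers: Sequence[MarkerRecord] | None = None
) -> tuple[dict[str, str], list[MarkerRecord], pd.DataFrame]:
    """Build toy reference chromosomes with embedded marker flanks and probes.

    Each marker gets an odd-length flank centered on its reference base at a
    position rescaled onto the toy chromosome.  A deterministic count
    ``round(duplication_fraction * n_markers)`` of flanks is copied to a
    second random locus (homoeologue mimic).  Returns (sequences,
    markers-with-flanks, probe table with 3'-end distance and GC content).
    """
    rng = cfg.stream("reference")
    if markers is None:
        markers = _marker_positions(cfg, rng)
    half = cfg.flank_length // 2
    if cfg.ref_chrom_length_bp < cfg.flank_length:
        raise ValueError("reference chromosomes shorter than the flank length")
    chroms = sorted({m.chrom for m in markers})
    bases = np.array(list("ACGT"))
    seqs = {
        c: rng.choice(4, size=cfg.ref_chrom_length_bp) for c in chroms
    }

    slots = cfg.ref_chrom_length_bp // cfg.flank_length
    counts: dict[str, int] = {c: sum(m.chrom == c for m in markers) for c in chroms}
    for c, k in counts.items():
        if k > slots:
            raise ValueError(
                f"more markers ({k}) than non-overlapping flank positions "
                f"({slots}) on toy chromosome {c}"
            )
    toy_pos: dict[str, int] = {}
    out_markers: list[MarkerRecord] = []
    for c in chroms:
        ms = [m for m in markers if m.chrom == c]
        # non-overlapping, position-ordered slots on the toy chromosome
        chosen = rng.choice(slots, size=counts[c], replace=False)
        chosen.sort()
        for m, slot in zip(sorted(ms, key=lambda m: m.pos), chosen):
            center = int(slot) * cfg.flank_length + half  # 0-based center
            seqs[c][center] = int(np.where(bases == m.ref_allele)[0][0])
            toy_pos[m.id] = center

    probe_rows = []
    dup_quota = int(round(cfg.duplication_fraction * len(markers)))
    dup_ids = set(
        rng.choice([m.id for m in markers], size=dup_quota, replace=False).tolist()
    ) if dup_quota else set()
    for m in markers:
        c = m.chrom
        center = toy_pos[m.id]
        flank = "".join(bases[seqs[c][center - half : center + half + 1]])
        out_markers.append(replace(m, flank=flank))
        # one probe upstream of the SNP, 3' end 5-25 bp away
        d3 = int(rng.integers(5, 26))
        pstart = center - d3 - cfg.probe_length
        if pstart < 0:
            pstart, d3 = 0, center - cfg.probe_length
        probe_seq = "".join(bases[seqs[c][pstart : pstart + cfg.probe_length]])
        gc = (probe_seq.count("G") + probe_seq.count("C")) / len(probe_seq)
        probe_rows.append(
            {
                "marker_id": m.id,
                "probe_seq": probe_seq,
                "strand": "+",
                "distance_3prime": d3,
                "gc_fraction": gc,
            }
        )
    seq_strs = {c: "".join(bases[v]) for c, v in seqs.items()}
    # homoeologue mimic: duplicated flanks reappear once on a decoy contig,
    # separated by random spacers so no new accidental matches arise
    if dup_ids:
        parts = []
        for m in out_markers:
            if m.id in dup_ids:
                spacer = "".join(bases[rng.integers(0, 4, size=20)])
                parts.append(m.flank + spacer)
        seq_strs["chrUn_decoy"] = "".join(parts)
    return seq_strs, out_markers, pd.DataFrame(probe_rows)
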