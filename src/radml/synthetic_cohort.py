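"""Synthetic paired methylation/expression cohorts with known ground truth.

Two generators live here:

``generate_cohort``
    A stochastic two-group cohort: a toy genome, a 450K-style manifest,
    beta values drawn on the logit scale (so planted mean differences near
    the [0,1] boundary stay attainable), negative-binomial RNA-seq counts,
    and planted methylation-expression couplings in which the NB log-mean
    is linear in the standardized logit-beta at the partner CpG.  Because
    the link is strictly monotone in the latent methylation level, the
    planted association is exactly the kind of rank (Spearman) dependence
    the analysis assumes.  The slope needed to hit a target Spearman
    magnitude was calibrated once by Monte-Carlo (4e5 samples at the
    default NB dispersion and mean expression) and is interpolated from
    the frozen grid below.

``generate_demo_fixture``
    A deterministic discovery + validation cohort pair whose per-stage
    bookkeeping (raDML totals, the coding-removal cascade, the
    intergenic/ncRNA and hypo/hyper splits, the significant-pair sign
    pattern and the validation replication counts) is fixed by
    construction: planted raDMLs have complete group separation, planted
    significant pairs are strictly monotone, and null pairs use a fixed
    low-rank-correlation permutation pattern.  The seed drives only
    rank-preserving micro-jitter, so every count is reproduced for any
    seed.

All randomness flows from ``SimulationParams.seed`` / the fixture seed;
there is no hidden global state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import log, pi, sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_data import (
    BetaMatrix,
    CountsMatrix,
    GeneModel,
    ProbeRecord,
    RegulatoryTrack,
    SampleMeta,
    ValidationError,
    write_gene_annotation,
    write_manifest,
    write_matrix,
    write_sample_meta,
    write_tracks,
)

logger = logging.getLogger(__name__)

#: the six ChromHMM states plus open-chromatin / enhancer track names
TRACK_NAMES = (
    "TssA", "TssAFlnk", "TssBiv", "EnhG", "Enh", "EnhBiv",
    "DNase", "enhancer", "super_enhancer",
)

# Frozen Monte-Carlo calibration of the coupling slope b (NB log-mean
# linear in standardized logit-beta) against the attained Spearman
# magnitude, at NB dispersion 0.2 and mean expression log(100); 4e5
# samples per grid point.
_CALIB_SLOPE = np.array(
    [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 4.0]
)
_CALIB_RHO = np.array(
    [0.0, 0.1965, 0.3738, 0.5165, 0.6251, 0.7072, 0.7656, 0.8457,
     0.8917, 0.9266, 0.9465, 0.9681, 0.9783, 0.9839, 0.9887]
)


def slope_for_rho(rho: float) -> float:
    """Coupling slope whose attained Spearman magnitude is ``|rho|``, signed."""
    mag = abs(rho)
    if mag >= _CALIB_RHO[-1]:
        b = _CALIB_SLOPE[-1]
    else:
        b = float(np.interp(mag, _CALIB_RHO, _CALIB_SLOPE))
    return b if rho >= 0 else -b


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the stochastic cohort generator; see docs/methods.md."""

    n_per_group: int = 25
    n_probes: int = 2000
    n_genes: int = 300
    frac_dml: float = 0.05
    delta_planted: float = 0.12
    rho_planted: float = 0.7
    frac_coupled_pairs: float = 0.5
    nb_dispersion: float = 0.2
    mean_log_expression: float = log(100.0)
    sd_log_expression: float = 1.0
    beta_logit_sd: float = 0.4
    age_range: tuple[float, float] = (35.0, 75.0)
    n_chroms: int = 2
    chrom_length: int = 30_000_000
    frac_failed_probes: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dml", "frac_coupled_pairs", "frac_failed_probes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        if not 0.0 < self.delta_planted < 1.0:
            raise ValidationError("delta_planted must lie in (0,1)")
        if not -1.0 < self.rho_planted < 1.0:
            raise ValidationError("rho_planted must lie in (-1,1)")
        if self.n_per_group < 2 or self.n_probes < 1 or self.n_genes < 1:
            raise ValidationError("cohort dimensions too small")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if not 1 <= self.n_chroms <= 3:
            raise ValidationError("n_chroms must be 1..3")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth tables."""

    manifest: list[ProbeRecord]
    genes: list[GeneModel]
    beta: BetaMatrix
    detection_p: pd.DataFrame
    counts: CountsMatrix
    meta: list[SampleMeta]
    tracks: list[RegulatoryTrack]
    truth_dml: pd.DataFrame    # probe_id, true_delta, direction
    truth_pairs: pd.DataFrame  # probe_id, gene_id, rho_sign, slope, distance_kb

    def __post_init__(self) -> None:
        probe_ids = {p.probe_id for p in self.manifest}
        gene_ids = {g.gene_id for g in self.genes}
        if len(self.truth_dml) and not set(self.truth_dml.probe_id) <= probe_ids:
            raise ValidationError("truth_dml references unknown probes")
        if len(self.truth_pairs):
            if not set(self.truth_pairs.probe_id) <= probe_ids:
                raise ValidationError("truth_pairs references unknown probes")
            if not set(self.truth_pairs.gene_id) <= gene_ids:
                raise ValidationError("truth_pairs references unknown genes")
            if (self.truth_pairs.distance_kb.abs() > 1000).any():
                raise ValidationError("planted pair outside the 1 Mb window")


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

_BIOTYPE_MIX = (
    ("protein_coding", 0.65), ("lncRNA", 0.15), ("antisense", 0.08),
    ("lincRNA", 0.06), ("other_ncRNA", 0.06),
)
_MIN_GENE_LEN, _MAX_GENE_LEN = 2_000, 15_000
_CHROM_MARGIN = 100_000


def generate_genome(
    params: SimulationParams, seed: int | None = None
) -> tuple[list[GeneModel], list[RegulatoryTrack]]:
    """A toy annotation: genes on 1-3 chromosomes plus regulatory tracks."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return _build_genome(params, rng)


def _build_genome(params, rng) -> tuple[list[GeneModel], list[RegulatoryTrack]]:
    per_chrom = np.array_split(np.arange(params.n_genes), params.n_chroms)
    usable = params.chrom_length - 2 * _CHROM_MARGIN
    genes: list[GeneModel] = []
    names, probs = zip(*_BIOTYPE_MIX)
    biotypes = rng.choice(names, size=params.n_genes, p=probs)
    strands = rng.choice(["+", "-"], size=params.n_genes)
    for ci, idx in enumerate(per_chrom):
        if len(idx) == 0:
            continue
        stride = usable // len(idx)
        if stride < _MAX_GENE_LEN + 1_000:
            raise ValidationError(
                f"{len(idx)} genes do not fit on a {params.chrom_length} bp "
                "chromosome; increase chrom_length or reduce n_genes"
            )
        for j, gi in enumerate(idx):
            length = int(rng.integers(_MIN_GENE_LEN, _MAX_GENE_LEN))
            start = _CHROM_MARGIN + j * stride + int(
                rng.integers(0, stride - length)
            )
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:05d}",
                    name=f"G{gi:05d}",
                    chrom=f"chr{ci + 1}",
                    start=start,
                    end=start + length,
                    strand=str(strands[gi]),
                    biotype=str(biotypes[gi]),
                )
            )
    tracks = []
    n_iv = max(3, params.n_genes // 5)
    for name in TRACK_NAMES:
        lo, hi = (10_000, 40_000) if name == "super_enhancer" else (500, 5_000)
        ivs = []
        for _ in range(n_iv):
            chrom = f"chr{int(rng.integers(1, params.n_chroms + 1))}"
            start = int(rng.integers(0, params.chrom_length - hi))
            ivs.append((chrom, start, start + int(rng.integers(lo, hi))))
        tracks.append(RegulatoryTrack(name, tuple(sorted(ivs))))
    return genes, tracks


# ---------------------------------------------------------------------------
# stochastic cohort
# ---------------------------------------------------------------------------

def _logit(p):
    return np.log(p / (1.0 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit_mu(mean_beta, sd):
    # E[sigmoid(N(mu, sd))] ~ sigmoid(mu / sqrt(1 + pi sd^2 / 8)); invert so
    # the realized mean beta matches the requested one.
    return _logit(mean_beta) * sqrt(1.0 + pi * sd * sd / 8.0)


def _nb_sample(rng, mean, dispersion):
    """NB via gamma-Poisson; var = mean + dispersion * mean^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)


def _gene_overlaps(genes: Sequence[GeneModel]):
    """chrom -> (sorted starts, ends, index) for point-in-gene lookup."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: g.start)
        out[chrom] = (np.array([g.start for g in glist]),
                      np.array([g.end for g in glist]), glist)
    return out


def _genes_overlapping(index, chrom: str, pos: int) -> list[GeneModel]:
    if chrom not in index:
        return []
    starts, ends, glist = index[chrom]
    hi = int(np.searchsorted(starts, pos, side="right"))
    # genes are near-disjoint in the toy genome; a short back-scan suffices
    return [glist[i] for i in range(max(0, hi - 5), hi) if ends[i] > pos]


def generate_cohort(
    params: SimulationParams,
    genome: tuple[list[GeneModel], list[RegulatoryTrack]] | None = None,
) -> SyntheticCohort:
    """Draw a discovery cohort with planted DMLs and coupled cis pairs."""
    rng = np.random.default_rng(params.seed)
    genes, tracks = genome if genome is not None else _build_genome(params, rng)
    gene_index = _gene_overlaps(genes)

    # --- probes and manifest -------------------------------------------------
    chroms = rng.integers(1, params.n_chroms + 1, size=params.n_probes)
    positions = rng.integers(1_000, params.chrom_length - 1_000,
                             size=params.n_probes)
    manifest: list[ProbeRecord] = []
    for i in range(params.n_probes):
        chrom = f"chr{chroms[i]}"
        overlapping = _genes_overlapping(gene_index, chrom, int(positions[i]))
        manifest.append(
            ProbeRecord(
                probe_id=f"cg{i:07d}",
                chrom=chrom,
                pos=int(positions[i]),
                strand="+",
                manifest_genes=tuple((g.name, g.biotype) for g in overlapping),
            )
        )

    # --- planted DMLs --------------------------------------------------------
    n_dml = int(round(params.frac_dml * params.n_probes))
    dml_idx = rng.choice(params.n_probes, size=n_dml, replace=False)
    dml_signs = rng.choice([-1.0, 1.0], size=n_dml)
    truth_dml = pd.DataFrame(
        {
            "probe_id": [manifest[i].probe_id for i in dml_idx],
            "true_delta": dml_signs * params.delta_planted,
            "direction": np.where(dml_signs > 0, "hyper", "hypo"),
        }
    )

    # --- planted coupled pairs ----------------------------------------------
    # couple only DML probes free of protein-coding overlap: pairs planted at
    # probes the coding filter removes would never reach the pair stage
    n_coupled = int(round(params.frac_coupled_pairs * n_dml))
    pair_rows = []
    if n_coupled > 0:
        order = rng.permutation(len(dml_idx))
        used_genes: set[str] = set()
        for k in order:
            if len(pair_rows) >= n_coupled:
                break
            probe = manifest[dml_idx[k]]
            if probe.has_coding_assignment():
                continue
            nearby = [
                g for g in genes
                if g.chrom == probe.chrom
                and abs(g.tss() - probe.pos) <= 1_000_000
                and g.gene_id not in used_genes
                and not (g.start <= probe.pos < g.end)
            ]
            if not nearby:
                continue
            gene = nearby[int(rng.integers(len(nearby)))]
            used_genes.add(gene.gene_id)
            sign = float(rng.choice([-1.0, 1.0]))
            pair_rows.append(
                {
                    "probe_id": probe.probe_id,
                    "gene_id": gene.gene_id,
                    "rho_sign": sign,
                    "slope": sign * slope_for_rho(params.rho_planted),
                    "distance_kb": (gene.tss() - probe.pos) / 1000.0,
                }
            )
        if not pair_rows:
            raise ValidationError(
                "no gene within 1 Mb of any DML probe; place genes more "
                "densely (increase n_genes or reduce chrom_length)"
            )
        if len(pair_rows) < n_coupled:
            logger.warning(
                "planted %d coupled pairs of %d requested (cis gene scarcity)",
                len(pair_rows), n_coupled,
            )
    truth_pairs = pd.DataFrame(
        pair_rows, columns=["probe_id", "gene_id", "rho_sign", "slope",
                            "distance_kb"]
    )

    beta, detp, counts, meta = _sample_cohort(
        params, rng, manifest, genes, truth_dml, truth_pairs,
        sample_prefix="S", cohort="discovery",
    )
    return SyntheticCohort(manifest, genes, beta, detp, counts, meta,
                           tracks, truth_dml, truth_pairs)


def _sample_cohort(params, rng, manifest, genes, truth_dml, truth_pairs,
                   sample_prefix, cohort):
    """Sample beta/detP/counts/meta given planted truth tables."""
    n = 2 * params.n_per_group
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n)]
    groups = ["A"] * params.n_per_group + ["B"] * params.n_per_group
    ages = rng.uniform(*params.age_range, size=n)
    meta = [
        SampleMeta(sample_ids[i], groups[i], float(round(ages[i], 1)),
                   er_status="neg", cohort=cohort)
        for i in range(n)
    ]

    probe_ids = [p.probe_id for p in manifest]
    delta_by_probe = dict(zip(truth_dml.probe_id, truth_dml.true_delta))
    n_probes = len(manifest)
    d = params.delta_planted
    m0 = rng.uniform(0.2 + d, 0.8 - d, size=n_probes)
    mean_a = m0.copy()
    mean_b = m0.copy()
    for i, pid in enumerate(probe_ids):
        td = delta_by_probe.get(pid)
        if td is not None:
            mean_a[i] = m0[i] + td / 2.0
            mean_b[i] = m0[i] - td / 2.0
    sd = params.beta_logit_sd
    mu = np.empty((n_probes, n))
    mu[:, : params.n_per_group] = _logit_mu(mean_a, sd)[:, None]
    mu[:, params.n_per_group:] = _logit_mu(mean_b, sd)[:, None]
    logit_beta = rng.normal(mu, sd)
    beta_values = _sigmoid(logit_beta)
    beta = BetaMatrix(pd.DataFrame(beta_values, index=probe_ids,
                                   columns=sample_ids))

    # well-detected probes sit far below both QC thresholds (0.05 / 1e-5)
    detp_values = rng.uniform(0.0, 1e-7, size=(n_probes, n))
    n_fail = int(round(params.frac_failed_probes * n_probes))
    if n_fail:
        fail_idx = rng.choice(n_probes, size=n_fail, replace=False)
        for i in fail_idx:
            cols = rng.choice(n, size=int(0.6 * n) + 1, replace=False)
            detp_values[i, cols] = rng.uniform(0.2, 0.8, size=len(cols))
    detp = pd.DataFrame(detp_values, index=probe_ids, columns=sample_ids)

    # expression: NB log-mean linear in standardized logit-beta for coupled
    # genes, flat for the rest
    gene_ids = [g.gene_id for g in genes]
    probe_row = {pid: i for i, pid in enumerate(probe_ids)}
    mu0 = rng.normal(params.mean_log_expression, params.sd_log_expression,
                     size=len(genes))
    log_mean = np.tile(mu0[:, None], (1, n))
    gene_row = {gid: i for i, gid in enumerate(gene_ids)}
    for row in truth_pairs.itertuples():
        z = logit_beta[probe_row[row.probe_id]]
        z = (z - z.mean()) / z.std()
        log_mean[gene_row[row.gene_id]] = mu0[gene_row[row.gene_id]] + row.slope * z
    counts_values = _nb_sample(rng, np.exp(log_mean), params.nb_dispersion)
    counts = CountsMatrix(pd.DataFrame(counts_values, index=gene_ids,
                                       columns=sample_ids))
    return beta, detp, counts, meta


def generate_validation(
    params: SimulationParams,
    discovery: SyntheticCohort,
    seed: int | None = None,
    frac_discordant_probes: float = 0.0,
    frac_discordant_pairs: float = 0.0,
) -> SyntheticCohort:
    """A second cohort on the discovery genome/manifest with fresh samples.

    Mirrors an external validation set sharing the array design: the same
    probes and genes, new samples, and (optionally) a configurable
    fraction of planted DML signs / coupling signs flipped to exercise the
    concordance and replication checks.
    """
    rng = np.random.default_rng((params.seed if seed is None else seed) + 7919)
    truth_dml = discovery.truth_dml.copy()
    if frac_discordant_probes > 0 and len(truth_dml):
        k = int(round(frac_discordant_probes * len(truth_dml)))
        flip = rng.choice(len(truth_dml), size=k, replace=False)
        truth_dml.loc[truth_dml.index[flip], "true_delta"] *= -1.0
        truth_dml["direction"] = np.where(truth_dml.true_delta > 0,
                                          "hyper", "hypo")
    truth_pairs = discovery.truth_pairs.copy()
    if frac_discordant_pairs > 0 and len(truth_pairs):
        k = int(round(frac_discordant_pairs * len(truth_pairs)))
        flip = rng.choice(len(truth_pairs), size=k, replace=False)
        truth_pairs.loc[truth_pairs.index[flip], ["rho_sign", "slope"]] *= -1.0
    beta, detp, counts, meta = _sample_cohort(
        params, rng, discovery.manifest, discovery.genes, truth_dml,
        truth_pairs, sample_prefix="V", cohort="validation",
    )
    return SyntheticCohort(discovery.manifest, discovery.genes, beta, detp,
                           counts, meta, discovery.tracks, truth_dml,
                           truth_pairs)


# ---------------------------------------------------------------------------
# deterministic demonstration fixture
# ---------------------------------------------------------------------------

# Per-stage bookkeeping the fixture reproduces (discovery + validation).
FIXTURE_COUNTS = {
    "total_radml": 396,
    "manifest_coding": 276,
    "uncharacterized": 120,
    "annotation_coding": 24,
    "noncoding_survivors": 96,
    "intergenic": 59,
    "ncRNA": 37,
    "hypo": 58,
    "hyper": 38,
    "significant_pairs": 39,
    "unique_cpgs": 23,
    "unique_genes": 36,
    "positive_pairs": 25,
    "testable_in_validation": 28,
    "replicated": 20,
    "probes_in_validation": 59,
    "discordant_probes": 1,
}

_N_NULL_PROBES = 604
_N_SAMPLES_PER_GROUP = 25
_RAMP_SPREAD = 0.04
_JITTER = 1e-7
# fixed permutation with |Spearman| <= 0.04 against both planted beta rank
# profiles: expression pattern for null (non-significant) pairs
_NULL_STRIDE = 11

# cis-pair multiplicities for the 17 solo pair-CpGs (sum 33); the remaining
# 6 pair-CpGs form 3 duos sharing one gene each (6 pairs, 3 genes), giving
# 39 pairs over 23 CpGs and 36 unique genes
_SOLO_MULT = (3, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1)
_N_SOLO = len(_SOLO_MULT)
_N_DUOS = 3
_PAIR_OFFSETS = (150_000, -220_000, 310_000)  # TSS offsets for solo partners
_NULL_OFFSETS = (430_000, -610_000)           # TSS offsets for null partners


def _ramp(mean: float) -> np.ndarray:
    k = np.arange(_N_SAMPLES_PER_GROUP)
    return mean - _RAMP_SPREAD / 2 + _RAMP_SPREAD * k / (_N_SAMPLES_PER_GROUP - 1)


def _group_beta(mean_a: float, mean_b: float) -> np.ndarray:
    """50 beta values, group A first; complete separation when means differ."""
    return np.concatenate([_ramp(mean_a), _ramp(mean_b)])


def _beta_ranks(delta_sign: float) -> np.ndarray:
    """Sample ranks (1..50) of a planted probe's beta values."""
    within = np.arange(1, _N_SAMPLES_PER_GROUP + 1)
    if delta_sign > 0:  # group A higher
        return np.concatenate([within + _N_SAMPLES_PER_GROUP, within])
    return np.concatenate([within, within + _N_SAMPLES_PER_GROUP])


def _null_pattern(n: int = 50) -> np.ndarray:
    return (np.arange(n) * _NULL_STRIDE) % n


@dataclass(frozen=True)
class _FixturePlan:
    """Static layout shared by the fixture's discovery and validation arms."""

    probes: list[ProbeRecord]
    genes: list[GeneModel]
    tracks: list[RegulatoryTrack]
    survivor_ids: list[str]
    survivor_sign: dict[str, float]     # +1 hyper / -1 hypo in group A
    survivor_delta: dict[str, float]
    survivor_mean: dict[str, float]
    radml_ids: list[str]                # all 396
    radml_sign: dict[str, float]
    radml_delta: dict[str, float]
    radml_mean: dict[str, float]
    null_ids: list[str]
    pair_list: list[tuple[str, str, float]]  # (probe, gene, rho_sign)
    validation_probe_ids: list[str]     # 59 survivors measured in validation
    discordant_probe: str
    dropped_genes: set[str]             # genes absent from validation counts
    nonreplicating_genes: set[str]      # null expression in validation
    null_gene_ids: list[str]
    host_gene_ids: list[str]


def _build_fixture_plan() -> _FixturePlan:
    deltas = (0.105, 0.11, 0.12, 0.13)
    means = (0.35, 0.45, 0.55, 0.65)

    # --- survivor probes on chr1 -------------------------------------------
    survivor_pos: list[int] = []
    pos = 2_000_000
    duo_seconds = {18, 20, 22}  # second members of the 3 duos (CpGs 17..22)
    for i in range(96):
        if i in duo_seconds:
            pos = survivor_pos[-1] + 800_000
        elif i > 0:
            pos = survivor_pos[-1] + 2_600_000
        survivor_pos.append(pos)

    survivor_ids = [f"cgS{i:04d}" for i in range(96)]
    survivor_sign = {
        pid: (-1.0 if i < 58 else 1.0) for i, pid in enumerate(survivor_ids)
    }
    survivor_delta = {pid: deltas[i % 4] for i, pid in enumerate(survivor_ids)}
    survivor_mean = {pid: means[i % 4] for i, pid in enumerate(survivor_ids)}

    genes: list[GeneModel] = []
    probes: list[ProbeRecord] = []
    for i, pid in enumerate(survivor_ids):
        probes.append(ProbeRecord(pid, "chr1", survivor_pos[i], "+"))
        if i >= 59:  # ncRNA survivors sit inside a small lncRNA gene
            c = survivor_pos[i]
            genes.append(GeneModel(f"NC{i:04d}", f"NC{i:04d}", "chr1",
                                   c - 500, c + 1500, "+", "lncRNA"))
    host_gene_ids = [g.gene_id for g in genes]

    # --- cis pairs -----------------------------------------------------------
    # solo CpGs 0..16 carry 33 private partner genes; duos 17..22 share 3
    pair_list: list[tuple[str, str, float]] = []
    pair_biotypes = ["protein_coding"] * 27 + [
        "antisense", "antisense", "antisense", "lincRNA", "lncRNA", "lncRNA",
    ]  # 33 private partners: 27 coding + 6 noncoding RNAs
    gnum = 0
    for j, mult in enumerate(_SOLO_MULT):
        c = survivor_pos[j]
        for k in range(mult):
            tss = c + _PAIR_OFFSETS[k]
            gid = f"PG{gnum:04d}"
            genes.append(GeneModel(gid, gid, "chr1", tss, tss + 5_000, "+",
                                   pair_biotypes[gnum % len(pair_biotypes)]))
            pair_list.append((survivor_ids[j], gid, 0.0))  # sign filled below
            gnum += 1
    shared_gene_ids = []
    for dd in range(_N_DUOS):
        j1, j2 = 17 + 2 * dd, 18 + 2 * dd
        mid = (survivor_pos[j1] + survivor_pos[j2]) // 2
        gid = f"SG{dd:02d}"
        shared_gene_ids.append(gid)
        genes.append(GeneModel(gid, gid, "chr1", mid, mid + 5_000, "+",
                               "protein_coding"))
        pair_list.append((survivor_ids[j1], gid, 0.0))
        pair_list.append((survivor_ids[j2], gid, 0.0))

    # sign pattern: 25 positive, 14 negative (the 6 duo pairs negative)
    signed = []
    for idx, (pid, gid, _) in enumerate(pair_list):
        if gid.startswith("SG"):
            sign = -1.0
        else:
            sign = 1.0 if idx < 25 else -1.0
        signed.append((pid, gid, sign))
    pair_list = signed

    # --- null partner genes near every survivor ------------------------------
    null_gene_ids = []
    for i in range(96):
        c = survivor_pos[i]
        for k, off in enumerate(_NULL_OFFSETS):
            gid = f"NG{i:04d}_{k}"
            null_gene_ids.append(gid)
            genes.append(GeneModel(gid, gid, "chr1", c + off, c + off + 4_000,
                                   "+", "protein_coding"))

    # --- removed raDMLs on chr2 ----------------------------------------------
    radml_ids = list(survivor_ids)
    radml_sign = dict(survivor_sign)
    radml_delta = dict(survivor_delta)
    radml_mean = dict(survivor_mean)
    for i in range(276):  # manifest protein-coding assignment
        pid = f"cgM{i:04d}"
        probes.append(ProbeRecord(pid, "chr2", 1_000_000 + i * 10_000, "+",
                                  ((f"MGENE{i:03d}", "protein_coding"),)))
        radml_ids.append(pid)
        radml_sign[pid] = -1.0 if i % 2 else 1.0
        radml_delta[pid] = deltas[i % 4]
        radml_mean[pid] = means[i % 4]
    for i in range(24):  # inside an updated-annotation coding gene
        start = 50_000_000 + i * 50_000
        gid = f"PC{i:03d}"
        genes.append(GeneModel(gid, gid, "chr2", start, start + 10_000, "+",
                               "protein_coding"))
        pid = f"cgA{i:04d}"
        probes.append(ProbeRecord(pid, "chr2", start + 500, "+"))
        radml_ids.append(pid)
        radml_sign[pid] = -1.0 if i % 2 else 1.0
        radml_delta[pid] = deltas[i % 4]
        radml_mean[pid] = means[i % 4]

    # --- null probes on chr3 --------------------------------------------------
    null_ids = [f"cgN{i:04d}" for i in range(_N_NULL_PROBES)]
    for i, pid in enumerate(null_ids):
        probes.append(ProbeRecord(pid, "chr3", 500_000 + i * 5_000, "+"))

    # --- regulatory tracks planted around the top pair-CpG -------------------
    top = survivor_pos[0]
    tracks = [
        RegulatoryTrack("Enh", (("chr1", top - 100, top + 100),)),
        RegulatoryTrack("super_enhancer", (("chr1", top - 5_000, top + 5_000),)),
        RegulatoryTrack("DNase", (("chr1", top - 200, top + 200),
                                  ("chr1", survivor_pos[1] - 200,
                                   survivor_pos[1] + 200))),
        RegulatoryTrack("enhancer", (("chr1", survivor_pos[1] - 300,
                                      survivor_pos[1] + 300),)),
        RegulatoryTrack("TssA", (("chr1", survivor_pos[2] - 100,
                                  survivor_pos[2] + 900),)),
        RegulatoryTrack("TssAFlnk", (("chr1", survivor_pos[3] + 2_000,
                                      survivor_pos[3] + 3_000),)),
        RegulatoryTrack("TssBiv", (("chr2", 50_000_000, 50_001_000),)),
        RegulatoryTrack("EnhG", (("chr1", survivor_pos[4] - 50,
                                  survivor_pos[4] + 450),)),
        RegulatoryTrack("EnhBiv", (("chr2", 1_000_000, 1_000_500),)),
    ]

    # --- validation design ----------------------------------------------------
    validation_probe_ids = survivor_ids[:59]   # the 59 intergenic survivors
    discordant_probe = survivor_ids[58]        # not a pair CpG (pair CpGs 0..22)
    private = [(i, p, g) for i, (p, g, _) in enumerate(pair_list)
               if not g.startswith("SG")]
    dropped_genes = {g for _, _, g in private[22:33]}        # 11 pairs lost
    nonreplicating_genes = {g for _, _, g in private[14:22]}  # 8 fail to replicate

    return _FixturePlan(
        probes=probes, genes=genes, tracks=tracks,
        survivor_ids=survivor_ids, survivor_sign=survivor_sign,
        survivor_delta=survivor_delta, survivor_mean=survivor_mean,
        radml_ids=radml_ids, radml_sign=radml_sign, radml_delta=radml_delta,
        radml_mean=radml_mean, null_ids=null_ids, pair_list=pair_list,
        validation_probe_ids=validation_probe_ids,
        discordant_probe=discordant_probe, dropped_genes=dropped_genes,
        nonreplicating_genes=nonreplicating_genes,
        null_gene_ids=null_gene_ids, host_gene_ids=host_gene_ids,
    )


def _fixture_beta(plan, probe_ids, sign_by_probe, rng, sample_ids):
    probe_by_id = {p.probe_id: p for p in plan.probes}
    rows = []
    for pid in probe_ids:
        if pid in plan.radml_delta:
            m, d = plan.radml_mean[pid], plan.radml_delta[pid]
            s = sign_by_probe[pid]
            rows.append(_group_beta(m + s * d / 2, m - s * d / 2))
        else:  # null probe: identical multisets in both groups
            m = 0.3 + 0.05 * (int(pid[3:]) % 9)
            rows.append(np.concatenate([_ramp(m), _ramp(m)]))
    values = np.array(rows)
    values = values + rng.uniform(-_JITTER, _JITTER, size=values.shape)
    assert probe_by_id  # layout sanity
    return BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))


def _fixture_counts(plan, sign_by_probe, gene_set, nonreplicating, sample_ids):
    """Counts: monotone in partner-CpG beta ranks for significant pairs,
    the fixed null pattern otherwise; a filler gene equalizes library
    sizes so logCPM is exactly monotone in counts."""
    pattern = _null_pattern()
    rows: dict[str, np.ndarray] = {}
    for pid, gid, rho_sign in plan.pair_list:
        if gid not in gene_set or gid in rows:
            continue
        if gid in nonreplicating:
            rows[gid] = 150 + pattern
            continue
        r = _beta_ranks(sign_by_probe[pid])
        rows[gid] = 200 + 3 * (r if rho_sign > 0 else 51 - r)
    for gid in plan.host_gene_ids:
        if gid in gene_set:
            rows[gid] = 120 + pattern
    for gid in plan.null_gene_ids:
        if gid in gene_set:
            rows[gid] = 100 + pattern
    gene_ids = sorted(rows)
    values = np.array([rows[g] for g in gene_ids])
    filler = values.sum(axis=0).max() + 1_000 - values.sum(axis=0)
    values = np.vstack([values, filler])
    return CountsMatrix(pd.DataFrame(values, index=gene_ids + ["FILLER"],
                                     columns=sample_ids))


def _fixture_meta(sample_ids, cohort):
    ages = 40.0 + np.arange(len(sample_ids)) % 31
    half = len(sample_ids) // 2
    return [
        SampleMeta(s, "A" if i < half else "B", float(ages[i]),
                   er_status="neg", cohort=cohort)
        for i, s in enumerate(sample_ids)
    ]


def generate_demo_fixture(seed: int = 0) -> tuple[SyntheticCohort, SyntheticCohort]:
    """The deterministic demonstration cohort pair (discovery, validation).

    Every bookkeeping count in :data:`FIXTURE_COUNTS` is fixed by
    construction; the seed only adds rank-preserving micro-jitter to beta
    values, so regenerating with the same seed is bit-identical and any
    seed reproduces the same counts.
    """
    rng = np.random.default_rng(seed)
    plan = _build_fixture_plan()
    n = 2 * _N_SAMPLES_PER_GROUP

    # discovery arm
    disc_samples = [f"S{i:03d}" for i in range(n)]
    disc_probe_ids = plan.radml_ids + plan.null_ids
    beta_d = _fixture_beta(plan, disc_probe_ids, plan.radml_sign, rng,
                           disc_samples)
    all_genes = {g.gene_id for g in plan.genes}
    counts_d = _fixture_counts(plan, plan.radml_sign, all_genes, set(),
                               disc_samples)
    detp_d = pd.DataFrame(1e-8, index=disc_probe_ids, columns=disc_samples)
    truth_dml_d = pd.DataFrame(
        {
            "probe_id": plan.radml_ids,
            "true_delta": [plan.radml_sign[p] * plan.radml_delta[p]
                           for p in plan.radml_ids],
            "direction": ["hyper" if plan.radml_sign[p] > 0 else "hypo"
                          for p in plan.radml_ids],
        }
    )
    probe_pos = {p.probe_id: p.pos for p in plan.probes}
    gene_tss = {g.gene_id: g.tss() for g in plan.genes}
    truth_pairs_d = pd.DataFrame(
        {
            "probe_id": [p for p, _, _ in plan.pair_list],
            "gene_id": [g for _, g, _ in plan.pair_list],
            "rho_sign": [s for _, _, s in plan.pair_list],
            "slope": [s for _, _, s in plan.pair_list],
            "distance_kb": [
                (gene_tss[g] - probe_pos[p]) / 1000.0
                for p, g, _ in plan.pair_list
            ],
        }
    )
    discovery = SyntheticCohort(
        manifest=plan.probes, genes=plan.genes, beta=beta_d,
        detection_p=detp_d, counts=counts_d,
        meta=_fixture_meta(disc_samples, "discovery"), tracks=plan.tracks,
        truth_dml=truth_dml_d, truth_pairs=truth_pairs_d,
    )

    # validation arm: 59 survivors (one sign-flipped) plus the null probes
    valid_samples = [f"V{i:03d}" for i in range(n)]
    valid_sign = dict(plan.radml_sign)
    valid_sign[plan.discordant_probe] *= -1.0
    valid_probe_ids = plan.validation_probe_ids + plan.null_ids
    beta_v = _fixture_beta(plan, valid_probe_ids, valid_sign, rng,
                           valid_samples)
    valid_gene_set = {
        g for _, g, _ in plan.pair_list if g not in plan.dropped_genes
    } | set(plan.null_gene_ids)
    counts_v = _fixture_counts(plan, valid_sign, valid_gene_set,
                               plan.nonreplicating_genes, valid_samples)
    detp_v = pd.DataFrame(1e-8, index=valid_probe_ids, columns=valid_samples)
    truth_dml_v = truth_dml_d[
        truth_dml_d.probe_id.isin(plan.validation_probe_ids)
    ].copy()
    flip = truth_dml_v.probe_id == plan.discordant_probe
    truth_dml_v.loc[flip, "true_delta"] *= -1.0
    truth_dml_v.loc[flip, "direction"] = "hypo"
    truth_pairs_v = truth_pairs_d[
        ~truth_pairs_d.gene_id.isin(plan.dropped_genes)
    ].copy()
    validation = SyntheticCohort(
        manifest=plan.probes, genes=plan.genes, beta=beta_v,
        detection_p=detp_v, counts=counts_v,
        meta=_fixture_meta(valid_samples, "validation"), tracks=plan.tracks,
        truth_dml=truth_dml_v, truth_pairs=truth_pairs_v,
    )
    return discovery, validation


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write every cohort file in the pipeline's on-disk formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(cohort.manifest, out / "manifest.csv")
    write_gene_annotation(cohort.genes, out / "genes.bed")
    write_matrix(cohort.beta, out / "beta.tsv")
    cohort.detection_p.to_csv(out / "detection_p.tsv", sep="\t",
                              index_label="probe")
    write_matrix(cohort.counts, out / "counts.tsv")
    write_sample_meta(cohort.meta, out / "meta.csv")
    write_tracks(cohort.tracks, out / "tracks.bed")
    cohort.truth_dml.to_csv(out / "truth_dml.tsv", sep="\t", index=False)
    cohort.truth_pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
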