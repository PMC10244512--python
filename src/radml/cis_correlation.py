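"""Cis CpG-gene pair enumeration, Spearman scanning and replication.

Genes whose strand-aware TSS lies within ``window`` (default 1 Mb, boundary
inclusive) of a CpG on the same chromosome form candidate pairs; for each
pair the Spearman correlation between beta values and logCPM expression is
computed and BH-adjusted over the full enumerated pair family.  Signed
distances follow the genome axis: ``distance_kb = (tss - cpg_pos) / 1000``,
negative when the TSS lies left of the CpG.

Replication in a second cohort recomputes rho within the testable subset
(pairs whose probe and gene are both measured there), applies BH within
that subset only, and flags a pair replicated when the correlation sign
matches discovery and the replication q-value clears the FDR threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dml_calling import DmlRecord, bh_fdr
from .genomic_data import BetaMatrix, GeneModel, ProbeRecord, ValidationError

logger = logging.getLogger(__name__)

#: minimum pairwise-complete observations for a testable correlation
MIN_SAMPLES = 4


@dataclass(frozen=True)
class CpgGenePair:
    """A cis CpG-gene pair with its methylation-expression correlation."""

    probe_id: str
    gene_id: str
    distance_kb: float
    rho: float = math.nan
    p_value: float = math.nan
    q_value: float = math.nan
    n_samples: int = 0
    replicated: str = "untestable"  # yes / no / untestable
    rho_validation: float = math.nan
    q_validation: float = math.nan


def enumerate_cis_pairs(
    probes: Sequence[ProbeRecord],
    genes: Sequence[GeneModel],
    window: int = 1_000_000,
) -> list[CpgGenePair]:
    """All (probe, gene) pairs with |TSS - CpG| <= ``window``, same chromosome.

    The window boundary is inclusive; pairs are deduplicated by
    (probe_id, gene_id) and returned in probe-then-gene order.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.tss())

    pairs: list[CpgGenePair] = []
    seen: set[tuple[str, str]] = set()
    for probe in probes:
        glist = by_chrom.get(probe.chrom, [])
        if not glist:
            continue
        tss = np.array([g.tss() for g in glist])
        lo = np.searchsorted(tss, probe.pos - window, side="left")
        hi = np.searchsorted(tss, probe.pos + window, side="right")
        for g in glist[lo:hi]:
            key = (probe.probe_id, g.gene_id)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(
                CpgGenePair(
                    probe_id=probe.probe_id,
                    gene_id=g.gene_id,
                    distance_kb=(g.tss() - probe.pos) / 1000.0,
                )
            )
    return pairs


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Midrank Spearman rho with a two-sided t-approximation p-value.

    Missing values are removed pairwise-complete; a constant vector yields
    ``(nan, nan)``; fewer than ``MIN_SAMPLES`` complete pairs is an error
    (callers mark such pairs untestable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < MIN_SAMPLES:
        raise ValidationError(
            f"need >= {MIN_SAMPLES} pairwise-complete observations, got {x.size}"
        )
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_pairs(
    pairs: Sequence[CpgGenePair],
    beta: BetaMatrix,
    logcpm: pd.DataFrame,
    fdr_thresh: float = 0.05,
) -> list[CpgGenePair]:
    """Spearman rho/p per pair with BH q over the full enumerated family.

    Pairs whose probe or gene is missing from the matrices, with a constant
    vector, or with too few complete observations are dropped with a logged
    warning.  Use :func:`significant_pairs` for the q < ``fdr_thresh``
    subset.
    """
    shared = [s for s in beta.sample_ids if s in set(logcpm.columns)]
    if len(shared) < MIN_SAMPLES:
        raise ValidationError(
            f"only {len(shared)} samples shared between beta and expression"
        )
    tested: list[CpgGenePair] = []
    pvals: list[float] = []
    bvals = beta.values[shared]
    evals = logcpm[shared]
    for pair in pairs:
        if pair.probe_id not in bvals.index or pair.gene_id not in evals.index:
            logger.warning(
                "pair %s/%s dropped: missing from matrices",
                pair.probe_id, pair.gene_id,
            )
            continue
        x = bvals.loc[pair.probe_id].to_numpy()
        y = evals.loc[pair.gene_id].to_numpy()
        n = int((~(np.isnan(x) | np.isnan(y))).sum())
        try:
            rho, p = spearman(x, y)
        except ValidationError:
            logger.warning(
                "pair %s/%s untestable: %d complete observations",
                pair.probe_id, pair.gene_id, n,
            )
            continue
        if math.isnan(rho):
            logger.warning(
                "pair %s/%s dropped: constant vector", pair.probe_id, pair.gene_id
            )
            continue
        tested.append(replace(pair, rho=rho, p_value=p, n_samples=n))
        pvals.append(p)
    qvals = bh_fdr(pvals)
    return [replace(pr, q_value=float(q)) for pr, q in zip(tested, qvals)]


def significant_pairs(
    pairs: Sequence[CpgGenePair], fdr_thresh: float = 0.05
) -> list[CpgGenePair]:
    return [p for p in pairs if p.q_value < fdr_thresh]


class ConcordanceResult(NamedTuple):
    table: pd.DataFrame
    n_available: int
    n_concordant: int
    n_discordant: int


def direction_consistency(
    dml_discovery: Sequence[DmlRecord],
    dml_validation: Sequence[DmlRecord],
) -> ConcordanceResult:
    """Delta-beta sign concordance for probes measured in both cohorts."""
    valid = {r.probe_id: r for r in dml_validation}
    rows = []
    for rec in dml_discovery:
        other = valid.get(rec.probe_id)
        if other is None:
            continue
        rows.append(
            {
                "probe_id": rec.probe_id,
                "delta_beta_discovery": rec.delta_beta,
                "delta_beta_validation": other.delta_beta,
                "concordant": np.sign(rec.delta_beta) == np.sign(other.delta_beta),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["probe_id", "delta_beta_discovery", "delta_beta_validation",
                 "concordant"],
    )
    n_conc = int(table["concordant"].sum()) if len(table) else 0
    return ConcordanceResult(table, len(table), n_conc, len(table) - n_conc)


def replicate_pairs(
    pairs_discovery: Sequence[CpgGenePair],
    beta_valid: BetaMatrix,
    logcpm_valid: pd.DataFrame,
    fdr_thresh: float = 0.05,
) -> list[CpgGenePair]:
    """Replication of discovery-significant pairs in a validation cohort.

    BH is applied within the testable subset only (a separate family from
    discovery).  ``replicated`` becomes ``yes`` when the validation rho has
    the discovery sign and the replication q-value is below ``fdr_thresh``;
    pairs absent from the validation matrices stay ``untestable``.
    """
    shared = [s for s in beta_valid.sample_ids if s in set(logcpm_valid.columns)]
    testable_idx: list[int] = []
    rhos: list[float] = []
    pvals: list[float] = []
    out = list(pairs_discovery)
    for i, pair in enumerate(out):
        if (
            pair.probe_id not in beta_valid.values.index
            or pair.gene_id not in logcpm_valid.index
        ):
            out[i] = replace(pair, replicated="untestable")
            continue
        x = beta_valid.values.loc[pair.probe_id, shared].to_numpy()
        y = logcpm_valid.loc[pair.gene_id, shared].to_numpy()
        try:
            rho, p = spearman(x, y)
        except ValidationError:
            out[i] = replace(pair, replicated="untestable")
            continue
        if math.isnan(rho):
            out[i] = replace(pair, replicated="untestable")
            continue
        testable_idx.append(i)
        rhos.append(rho)
        pvals.append(p)
    qvals = bh_fdr(pvals)
    for i, rho, q in zip(testable_idx, rhos, qvals):
        pair = out[i]
        ok = bool(np.sign(rho) == np.sign(pair.rho) and q < fdr_thresh)
        out[i] = replace(
            pair,
            replicated="yes" if ok else "no",
            rho_validation=float(rho),
            q_validation=float(q),
        )
    return out


# ---------------------------------------------------------------------------
# tabular round-trip (column order mirrors the published top-pairs table)
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "probe_id", "gene_id", "distance_kb", "rho", "p_value", "q_value",
    "n_samples", "replicated", "rho_validation", "q_validation",
]


def pairs_to_frame(pairs: Sequence[CpgGenePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(p, c) for c in _PAIR_COLUMNS} for p in pairs],
        columns=_PAIR_COLUMNS,
    )


def pairs_from_frame(df: pd.DataFrame) -> list[CpgGenePair]:
    return [
        CpgGenePair(
            probe_id=str(r.probe_id),
            gene_id=str(r.gene_id),
            distance_kb=float(r.distance_kb),
            rho=float(r.rho),
            p_value=float(r.p_value),
            q_value=float(r.q_value),
            n_samples=int(r.n_samples),
            replicated=str(r.replicated),
            rho_validation=float(r.rho_validation),
            q_validation=float(r.q_validation),
        )
        for r in df.itertuples()
    ]
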