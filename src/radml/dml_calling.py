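"""Detection-p QC, two-group per-probe testing and raDML calling.

A raDML (race-associated differentially methylated locus) is a CpG whose
mean beta difference between the two sample groups is at least
``delta_thresh`` in absolute value and whose Benjamini-Hochberg adjusted
Wilcoxon rank-sum p-value is below ``fdr_thresh``.  Delta-beta is defined
as mean(group A) - mean(group B), so ``direction == "hyper"`` means
hypermethylated in group A.

The sample-level detection filter implements the evidently intended rule —
a sample is retained only when more than ``frac`` of loci are well detected
(detection p < ``p_thresh``) — because the literal phrasing commonly used
for this filter ("samples with detection p < 1e-5 at more than 75% of loci
were removed") would discard the best-detected samples.  A warning noting
the adopted reading is logged once per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_data import (
    BetaMatrix,
    GeneModel,
    ProbeRecord,
    SampleMeta,
    ValidationError,
    group_levels,
)

logger = logging.getLogger(__name__)

#: region classes assigned to probes
REGION_CLASSES = ("protein_coding", "ncRNA", "intergenic")


@dataclass(frozen=True)
class DmlRecord:
    """Per-probe two-group test result."""

    probe_id: str
    mean_beta_a: float
    mean_beta_b: float
    delta_beta: float
    p_value: float
    q_value: float
    direction: str  # hyper/hypo w.r.t. group A
    is_radml: bool
    region_class: str = ""

    def __post_init__(self) -> None:
        if abs(self.delta_beta) > 1 + 1e-12:
            raise ValidationError(f"{self.probe_id}: |delta beta| > 1")


# ---------------------------------------------------------------------------
# detection-p QC
# ---------------------------------------------------------------------------

def filter_probes_by_detection(
    detp: pd.DataFrame, p_thresh: float = 0.05, frac: float = 0.5
) -> list[str]:
    """Probe ids retained by the locus-level detection filter.

    A probe is removed iff it fails detection (detP > ``p_thresh``) in
    strictly more than ``frac`` of samples ("more than half" is strict).
    """
    if detp.size == 0:
        raise ValidationError("empty detection-p matrix")
    n_fail = (detp > p_thresh).sum(axis=1)
    keep = n_fail <= frac * detp.shape[1]
    return list(detp.index[keep])


def filter_samples_by_detection(
    detp: pd.DataFrame, p_thresh: float = 1e-5, frac: float = 0.75
) -> list[str]:
    """Sample ids retained by the sample-level detection filter.

    A sample is retained iff strictly more than ``frac`` of loci are well
    detected (detP < ``p_thresh``).  See module docstring for why the
    retained/removed reading is inverted relative to the usual phrasing.
    """
    if detp.size == 0:
        raise ValidationError("empty detection-p matrix")
    logger.warning(
        "sample detection filter keeps samples with >%d%% well-detected loci "
        "(detP < %g); the commonly printed phrasing of this rule is inverted",
        int(frac * 100),
        p_thresh,
    )
    n_good = (detp < p_thresh).sum(axis=0)
    keep = n_good > frac * detp.shape[0]
    return list(detp.columns[keep])


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

#: largest pooled size for which the exact rank-sum null is enumerated
EXACT_MAX_N = 12


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact: bool | None = None
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test.

    Returns the rank-sum statistic of ``x`` (midranks for ties) and a
    two-sided p-value.  The asymptotic path uses the normal approximation
    with the exact (tie-corrected) permutation variance and a continuity
    correction equal to half the rank-sum support spacing; ``exact=True``
    (auto-selected when the pooled size is at most ``EXACT_MAX_N``)
    enumerates the permutation distribution, which is valid under ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValidationError("a group is empty after missing-data removal")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    if exact is None:
        exact = n <= EXACT_MAX_N
    if exact:
        return w, _exact_rank_sum_p(ranks, n1)
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:  # all pooled values identical
        return w, 1.0
    # continuity correction: half the rank-sum support spacing, which
    # midranks halve to 0.5 as soon as any tie is present
    h = 0.5 if tie_term == 0 else 0.25
    z = max(0.0, abs(w - mu) - h) / sqrt(var)
    return w, min(1.0, float(2.0 * stats.norm.sf(z)))


def _exact_rank_sum_p(ranks: np.ndarray, n1: int) -> float:
    """Exact two-sided p by enumerating all rank-sum assignments."""
    n = ranks.size
    mu = n1 * (ranks.sum() / n)  # E[W] under exchangeability, tie-safe
    obs = abs(ranks[:n1].sum() - mu)
    count = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
            count += 1
    return count / total


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# raDML calling
# ---------------------------------------------------------------------------

def call_radml(
    beta: BetaMatrix,
    meta: Sequence[SampleMeta],
    delta_thresh: float = 0.10,
    fdr_thresh: float = 0.05,
    group_a: str | None = None,
) -> list[DmlRecord]:
    """Per-probe two-group testing over a beta matrix.

    Returns one :class:`DmlRecord` per probe with Wilcoxon p, BH q computed
    over all tested probes, and delta beta = mean(A) - mean(B).  The
    ``is_radml`` flag applies the inclusive |delta beta| >= ``delta_thresh``
    and q < ``fdr_thresh`` rule.  ``group_a`` names the reference stratum
    (default: first group level in sorted order).
    """
    la, lb = group_levels(meta)
    if group_a is not None:
        if group_a not in (la, lb):
            raise ValidationError(f"group_a {group_a!r} not among levels ({la}, {lb})")
        la, lb = group_a, lb if group_a == la else la
    by_sample = {m.sample_id: m.group for m in meta}
    cols_a = [s for s in beta.sample_ids if by_sample.get(s) == la]
    cols_b = [s for s in beta.sample_ids if by_sample.get(s) == lb]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {len(cols_a)} vs {len(cols_b)}"
        )
    va = beta.values[cols_a].to_numpy()
    vb = beta.values[cols_b].to_numpy()
    mean_a = np.nanmean(va, axis=1)
    mean_b = np.nanmean(vb, axis=1)
    delta = mean_a - mean_b

    if not (np.isnan(va).any() or np.isnan(vb).any()):
        # complete data: vectorised tie-corrected normal approximation
        _, pvals = stats.mannwhitneyu(
            va, vb, axis=1, alternative="two-sided",
            use_continuity=True, method="asymptotic",
        )
        pvals = np.asarray(pvals, dtype=float)
    else:
        pvals = np.empty(len(beta.probe_ids))
        for i in range(va.shape[0]):
            _, pvals[i] = wilcoxon_rank_sum(va[i], vb[i], exact=False)
    qvals = bh_fdr(pvals)

    records = []
    for i, pid in enumerate(beta.probe_ids):
        d = float(delta[i])
        records.append(
            DmlRecord(
                probe_id=pid,
                mean_beta_a=float(mean_a[i]),
                mean_beta_b=float(mean_b[i]),
                delta_beta=d,
                p_value=float(pvals[i]),
                q_value=float(qvals[i]),
                direction="hyper" if d > 0 else "hypo",
                is_radml=bool(abs(d) >= delta_thresh and qvals[i] < fdr_thresh),
            )
        )
    return records


def radml_subset(records: Sequence[DmlRecord]) -> list[DmlRecord]:
    return [r for r in records if r.is_radml]


# ---------------------------------------------------------------------------
# noncoding classification cascade
# ---------------------------------------------------------------------------

class RegionClassifier:
    """Classify CpG positions against an updated gene annotation.

    Precedence: (1) any manifest protein-coding assignment; (2) overlap
    with a protein-coding gene body; (3) overlap with a noncoding-RNA
    gene; (4) intergenic.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self._chroms = {g.chrom for g in genes}
        if genes:
            self._ranges = pr.PyRanges(
                pd.DataFrame(
                    {
                        "Chromosome": [g.chrom for g in genes],
                        "Start": [g.start for g in genes],
                        "End": [g.end for g in genes],
                        "coding": [g.is_coding() for g in genes],
                    }
                )
            )
        else:
            self._ranges = None

    def classify(self, probe: ProbeRecord) -> str:
        if probe.has_coding_assignment():
            return "protein_coding"
        if probe.chrom not in self._chroms:
            logger.warning(
                "probe %s: chromosome %s absent from annotation; "
                "classified intergenic", probe.probe_id, probe.chrom,
            )
            return "intergenic"
        hits = self._ranges.overlap(
            pr.PyRanges(
                pd.DataFrame(
                    {
                        "Chromosome": [probe.chrom],
                        "Start": [probe.pos],
                        "End": [probe.pos + 1],
                    }
                )
            )
        )
        if len(hits) == 0:
            return "intergenic"
        return "protein_coding" if hits.df["coding"].any() else "ncRNA"

    def classify_many(self, probes: Sequence[ProbeRecord]) -> dict[str, str]:
        """Vectorised classification of many probes (one overlap join)."""
        out = {}
        remaining = []
        for p in probes:
            if p.has_coding_assignment():
                out[p.probe_id] = "protein_coding"
            elif p.chrom not in self._chroms:
                logger.warning(
                    "probe %s: chromosome %s absent from annotation; "
                    "classified intergenic", p.probe_id, p.chrom,
                )
                out[p.probe_id] = "intergenic"
            else:
                remaining.append(p)
                out[p.probe_id] = "intergenic"
        if remaining and self._ranges is not None:
            query = pr.PyRanges(
                pd.DataFrame(
                    {
                        "Chromosome": [p.chrom for p in remaining],
                        "Start": [p.pos for p in remaining],
                        "End": [p.pos + 1 for p in remaining],
                        "probe_id": [p.probe_id for p in remaining],
                    }
                )
            )
            joined = query.join(self._ranges)
            if len(joined) > 0:
                agg = joined.df.groupby("probe_id")["coding"].any()
                for pid, coding in agg.items():
                    out[pid] = "protein_coding" if coding else "ncRNA"
        return out


def classify_probe_region(probe: ProbeRecord, updated_genes: Sequence[GeneModel]) -> str:
    """Region class of one probe; see :class:`RegionClassifier`."""
    return RegionClassifier(updated_genes).classify(probe)


def noncoding_filter_cascade(
    radmls: Sequence[DmlRecord],
    probes: Mapping[str, ProbeRecord] | Sequence[ProbeRecord],
    updated_genes: Sequence[GeneModel],
) -> tuple[list[DmlRecord], pd.Series]:
    """Remove coding raDMLs in two stages and tabulate the bookkeeping.

    Stage 1 removes probes with at least one manifest protein-coding gene
    assignment; stage 2 removes probes whose position overlaps a
    protein-coding gene body in the updated annotation.  Survivors are
    split intergenic vs ncRNA and, by delta-beta sign, hypo vs hyper.

    Returns the surviving records (``region_class`` filled in) and a count
    table.  Counts always satisfy survivors = total - stage1 - stage2 and
    intergenic + ncRNA = hypo + hyper = survivors.
    """
    if not isinstance(probes, Mapping):
        probes = {p.probe_id: p for p in probes}
    missing = [r.probe_id for r in radmls if r.probe_id not in probes]
    if missing:
        raise ValidationError(f"raDML probes missing from manifest: {missing[:5]}")

    classifier = RegionClassifier(updated_genes)
    classes = classifier.classify_many([probes[r.probe_id] for r in radmls])

    removed_manifest = removed_annotation = 0
    survivors: list[DmlRecord] = []
    for rec in radmls:
        probe = probes[rec.probe_id]
        if probe.has_coding_assignment():
            removed_manifest += 1
            continue
        cls = classes[rec.probe_id]
        if cls == "protein_coding":
            removed_annotation += 1
            continue
        survivors.append(replace(rec, region_class=cls))

    counts = pd.Series(
        {
            "total_radml": len(radmls),
            "removed_manifest_coding": removed_manifest,
            "uncharacterized_after_manifest": len(radmls) - removed_manifest,
            "removed_annotation_coding": removed_annotation,
            "noncoding_survivors": len(survivors),
            "intergenic": sum(r.region_class == "intergenic" for r in survivors),
            "ncRNA": sum(r.region_class == "ncRNA" for r in survivors),
            "hypo": sum(r.direction == "hypo" for r in survivors),
            "hyper": sum(r.direction == "hyper" for r in survivors),
        },
        name="count",
    )
    return survivors, counts


# ---------------------------------------------------------------------------
# tabular round-trip
# ---------------------------------------------------------------------------

_DML_COLUMNS = [
    "probe_id", "mean_beta_a", "mean_beta_b", "delta_beta",
    "p_value", "q_value", "direction", "is_radml", "region_class",
]


def dml_to_frame(records: Sequence[DmlRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _DML_COLUMNS} for r in records],
                        columns=_DML_COLUMNS)


def dml_from_frame(df: pd.DataFrame) -> list[DmlRecord]:
    return [
        DmlRecord(
            probe_id=str(r.probe_id),
            mean_beta_a=float(r.mean_beta_a),
            mean_beta_b=float(r.mean_beta_b),
            delta_beta=float(r.delta_beta),
            p_value=float(r.p_value),
            q_value=float(r.q_value),
            direction=str(r.direction),
            is_radml=bool(r.is_radml),
            region_class=str(r.region_class) if pd.notna(r.region_class) else "",
        )
        for r in df.itertuples()
    ]
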