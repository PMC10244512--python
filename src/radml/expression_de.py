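"""Expression normalisation and covariate-adjusted differential expression.

Counts are normalised to log2 counts per million with a prior count:

    logCPM = log2( (count + prior) / (libsize + 2*prior) * 1e6 )

Differential expression between the two sample groups fits, per gene, an
ordinary linear model ``logCPM ~ group + age`` and tests the group
coefficient two-sided; the coefficient (group A vs B on the log2-CPM
scale) is reported as the log fold change.  This is a deliberately plain
substitute for a negative-binomial GLM with dispersion shrinkage: only the
effect direction and significance of a small, pre-selected gene set are
consumed downstream, where the two approaches agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dml_calling import bh_fdr
from .genomic_data import CountsMatrix, SampleMeta, ValidationError, group_levels


@dataclass(frozen=True)
class DeRecord:
    """Per-gene differential-expression result (group A vs B)."""

    gene_id: str
    log_fold_change: float
    p_value: float
    q_value: float
    covariates: tuple[str, ...] = ("age",)


def log_cpm(counts: CountsMatrix, prior: float = 0.5) -> pd.DataFrame:
    """Log2 counts-per-million with a prior count; deterministic."""
    values = counts.values.astype(float)
    libsize = values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample {zero.index[0]!r}")
    return np.log2((values + prior) / (libsize + 2 * prior) * 1e6)


def differential_expression(
    counts: CountsMatrix,
    meta: Sequence[SampleMeta],
    genes_tested: Sequence[str] | None = None,
    prior: float = 0.5,
    group_a: str | None = None,
) -> list[DeRecord]:
    """Two-group DE on logCPM with age adjustment, BH over ``genes_tested``.

    ``genes_tested`` restricts both the fits and the BH family (default:
    all genes in the matrix); ``group_a`` names the stratum whose effect
    sign is reported (default: first level in sorted order).
    """
    la, lb = group_levels(meta)
    if group_a is not None:
        if group_a not in (la, lb):
            raise ValidationError(f"group_a {group_a!r} not among levels")
        la = group_a
    by_sample = {m.sample_id: m for m in meta}
    samples = [s for s in counts.sample_ids if s in by_sample]
    if len(samples) < 4:
        raise ValidationError(f"only {len(samples)} samples with metadata")
    group_ind = np.array([1.0 if by_sample[s].group == la else 0.0 for s in samples])
    age = np.array([by_sample[s].age for s in samples])
    if group_ind.std() == 0:
        raise ValidationError("all samples in one group")
    design = np.column_stack([np.ones(len(samples)), group_ind, age])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("collinear design (group + age)")

    expr = log_cpm(counts, prior=prior)[samples]
    if genes_tested is None:
        genes_tested = list(expr.index)
    missing = [g for g in genes_tested if g not in expr.index]
    if missing:
        raise ValidationError(f"genes absent from counts matrix: {missing[:5]}")

    lfc = np.empty(len(genes_tested))
    pvals = np.empty(len(genes_tested))
    for i, gene in enumerate(genes_tested):
        fit = sm.OLS(expr.loc[gene].to_numpy(), design).fit()
        lfc[i] = fit.params[1]
        pvals[i] = fit.pvalues[1]
    qvals = bh_fdr(pvals)
    return [
        DeRecord(
            gene_id=g,
            log_fold_change=float(lfc[i]),
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
        )
        for i, g in enumerate(genes_tested)
    ]


_DE_COLUMNS = ["gene_id", "log_fold_change", "p_value", "q_value"]


def de_to_frame(records: Sequence[DeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in _DE_COLUMNS} for r in records],
        columns=_DE_COLUMNS,
    )
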