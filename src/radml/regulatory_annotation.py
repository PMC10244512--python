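"""Regulatory-context annotation of CpGs and run-level reporting.

Each CpG is intersected, as a 1-bp interval (optionally flanked), with
named interval tracks: chromatin states from a ChromHMM segmentation
(TssA, TssAFlnk, TssBiv, EnhG, Enh, EnhBiv), DNase I hypersensitive
sites, enhancers and super-enhancers.  The result is a boolean feature
matrix summarised as per-track counts and the number of CpGs falling in
at least one / at least two distinct feature classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .genomic_data import ProbeRecord, RegulatoryTrack

logger = logging.getLogger(__name__)

#: the six ChromHMM states singled out for interpretation
CHROMHMM_STATES = ("TssA", "TssAFlnk", "TssBiv", "EnhG", "Enh", "EnhBiv")

#: canonical track vocabulary; unknown names pass through with a log note
KNOWN_TRACKS = CHROMHMM_STATES + ("DNase", "enhancer", "super_enhancer")


@dataclass(frozen=True)
class FeatureMatrix:
    """Probe x track 0/1 membership flags."""

    flags: pd.DataFrame  # index probe ids, columns track names, values {0,1}

    @property
    def probe_ids(self) -> list[str]:
        return list(self.flags.index)

    @property
    def track_names(self) -> list[str]:
        return list(self.flags.columns)

    def feature_counts(self) -> pd.Series:
        """Number of distinct feature classes per probe (row sums)."""
        return self.flags.sum(axis=1)


def overlap_tracks(
    probes: Sequence[ProbeRecord],
    tracks: Sequence[RegulatoryTrack],
    flank: int = 0,
) -> FeatureMatrix:
    """Flag each probe for each track it intersects.

    A probe at position ``pos`` is the interval ``[pos - flank,
    pos + 1 + flank)``; overlap uses half-open interval intersection.
    Increasing ``flank`` can only add flags, never remove them.
    """
    for t in tracks:
        if t.name not in KNOWN_TRACKS:
            logger.info("track %r outside the canonical vocabulary; kept", t.name)
    flags = pd.DataFrame(
        0,
        index=pd.Index([p.probe_id for p in probes], name="probe_id"),
        columns=[t.name for t in tracks],
        dtype=np.int8,
    )
    if not probes or not tracks:
        return FeatureMatrix(flags)
    query = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [p.chrom for p in probes],
                "Start": [max(0, p.pos - flank) for p in probes],
                "End": [p.pos + 1 + flank for p in probes],
                "probe_id": [p.probe_id for p in probes],
            }
        )
    )
    for track in tracks:
        if not track.intervals:
            continue
        subject = pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": [iv[0] for iv in track.intervals],
                    "Start": [iv[1] for iv in track.intervals],
                    "End": [iv[2] for iv in track.intervals],
                }
            )
        )
        hits = query.overlap(subject)
        if len(hits) > 0:
            flags.loc[hits.df["probe_id"].unique(), track.name] = 1
    return FeatureMatrix(flags)


def summarize_features(fm: FeatureMatrix) -> pd.Series:
    """Per-track probe counts plus >=1 / >=2 distinct-feature tallies."""
    counts = fm.flags.sum(axis=0)
    per_probe = fm.feature_counts()
    out = {f"n_{name}": int(counts[name]) for name in fm.track_names}
    out["n_probes"] = len(fm.probe_ids)
    out["n_in_ge1_feature"] = int((per_probe >= 1).sum())
    out["n_in_ge2_features"] = int((per_probe >= 2).sum())
    return pd.Series(out, name="count")


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

#: files each upstream stage is expected to have written
STAGE_FILES = {
    "call-dml": ("dml.tsv", "cascade_counts.tsv"),
    "correlate": ("pairs.tsv",),
    "de": ("de.tsv",),
    "annotate": ("features.tsv",),
}


def build_report(
    dml: pd.DataFrame,
    cascade_counts: pd.Series,
    pairs: pd.DataFrame,
    de: pd.DataFrame,
    fm: FeatureMatrix,
    params: Mapping[str, object] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Assemble deterministic summary tables from the upstream outputs.

    The top-pairs table joins each significant pair with its probe's
    delta-beta and is sorted by q-value, then |rho| descending, then ids —
    a tabular analogue of a published top-pairs table.  When ``out_dir``
    is given, all tables plus a machine-readable run manifest are written;
    reruns with identical inputs produce byte-identical files.
    """
    delta_by_probe = dml.set_index("probe_id")["delta_beta"]
    sig = pairs[pairs["q_value"] < 0.05].copy()
    sig["delta_beta"] = sig["probe_id"].map(delta_by_probe)
    top = sig[
        ["probe_id", "gene_id", "distance_kb", "delta_beta", "rho", "q_value",
         "replicated"]
    ].sort_values(
        by=["q_value", "rho", "probe_id", "gene_id"],
        key=lambda c: -c.abs() if c.name == "rho" else c,
        kind="mergesort",
    ).reset_index(drop=True)

    replication = pd.Series(
        {
            "n_significant": len(sig),
            "n_testable": int((sig["replicated"] != "untestable").sum()),
            "n_replicated": int((sig["replicated"] == "yes").sum()),
            "n_not_replicated": int((sig["replicated"] == "no").sum()),
            "pct_positive_rho": round(
                100.0 * (sig["rho"] > 0).mean(), 1) if len(sig) else float("nan"),
        },
        name="count",
    )
    de_summary = pd.Series(
        {
            "n_genes_tested": len(de),
            "n_significant": int((de["q_value"] < 0.05).sum()),
            "n_down_in_A": int(((de["q_value"] < 0.05) & (de["log_fold_change"] < 0)).sum()),
            "n_up_in_A": int(((de["q_value"] < 0.05) & (de["log_fold_change"] > 0)).sum()),
        },
        name="count",
    )
    bundle: dict[str, pd.DataFrame | pd.Series] = {
        "cascade_counts": cascade_counts,
        "top_pairs": top,
        "replication_summary": replication,
        "de_summary": de_summary,
        "feature_summary": summarize_features(fm),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            path = out_dir / f"{name}.tsv"
            if isinstance(obj, pd.Series):
                obj.rename_axis("key").to_csv(path, sep="\t")
            else:
                obj.to_csv(path, sep="\t", index=False)
        manifest = {
            "parameters": dict(params or {}),
            "n_dml_records": int(len(dml)),
            "n_pairs": int(len(pairs)),
            "versions": _versions(),
        }
        (out_dir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
    return bundle


def report_from_dir(run_dir: str | Path, out_dir: str | Path | None = None):
    """Rebuild the report bundle from a stage-output directory.

    A missing upstream file raises an error naming the stage to rerun.
    """
    run_dir = Path(run_dir)
    for stage, files in STAGE_FILES.items():
        for fname in files:
            if not (run_dir / fname).exists():
                raise FileNotFoundError(
                    f"{run_dir / fname} is missing: rerun the `{stage}` stage"
                )
    dml = pd.read_csv(run_dir / "dml.tsv", sep="\t")
    cascade = pd.read_csv(
        run_dir / "cascade_counts.tsv", sep="\t", index_col=0
    )["count"]
    pairs = pd.read_csv(run_dir / "pairs.tsv", sep="\t")
    de = pd.read_csv(run_dir / "de.tsv", sep="\t")
    feat = pd.read_csv(run_dir / "features.tsv", sep="\t", index_col=0)
    fm = FeatureMatrix(feat)
    return build_report(dml, cascade, pairs, de, fm,
                        out_dir=out_dir or run_dir / "report")


def _versions() -> dict[str, str]:
    import scipy
    import radml

    return {
        "radml": getattr(radml, "__version__", "0"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
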