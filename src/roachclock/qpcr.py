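"""Relative gene expression by the comparative-Ct (2^-ddCt) convention.

Ct values of a gene of interest are first normalized against the reference
gene measured in the same sample (dCt = Ct_goi - Ct_ref), then against the
mean dCt of the same gene in the control group (ddCt); the expression ratio
is 2^-ddCt, i.e. perfect doubling per PCR cycle is assumed (no efficiency
correction).  Technical triplicates are averaged on the Ct scale before any
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "RelativeExpression",
    "delta_ct",
    "relative_expression",
    "relative_expression_table",
    "timepoint_profile",
    "average_technical_replicates",
]

#: assumed amplification factor per cycle
AMPLIFICATION = 2.0

CT_COLUMNS = ["sample", "gene", "group", "zt", "ct"]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: sample, gene, control/treatment group, optional ZT, Ct."""

    sample: str
    gene: str
    group: str  # "control" | "treatment" (free-form labels allowed)
    ct: float
    zt: float | None = None  # Zeitgeber time, hours

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"Ct must be finite and positive, got {self.ct}")


def delta_ct(goi_ct: float, ref_ct: float) -> float:
    """dCt = Ct(gene of interest) - Ct(reference gene), same sample."""
    if not (np.isfinite(goi_ct) and np.isfinite(ref_ct)):
        raise ValueError("both Ct values must be finite")
    return float(goi_ct) - float(ref_ct)


@dataclass(frozen=True)
class RelativeExpression:
    """Expression ratio of one sample relative to the control-group mean."""

    sample: str
    gene: str
    delta_ct: float
    delta_delta_ct: float

    @property
    def ratio(self) -> float:
        return float(AMPLIFICATION ** (-self.delta_delta_ct))


def relative_expression(sample_dct: float, control_mean_dct: float, sample: str = "", gene: str = "") -> RelativeExpression:
    """ddCt = dCt - mean control dCt; ratio = 2^-ddCt."""
    if not np.isfinite(control_mean_dct):
        raise ValueError("control-group mean dCt must be finite (empty control group?)")
    ddct = float(sample_dct) - float(control_mean_dct)
    return RelativeExpression(sample=sample, gene=gene, delta_ct=float(sample_dct), delta_delta_ct=ddct)


def average_technical_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Ct values per (sample, gene) on the Ct scale.

    Rows sharing sample and gene are treated as technical replicates of one
    reaction setup; group and ZT must be consistent within each set.
    """
    _check_columns(table)
    keys = ["sample", "gene", "group", "zt"]
    return table.groupby(keys, dropna=False, as_index=False)["ct"].mean()


def _check_columns(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")


def relative_expression_table(
    table: pd.DataFrame,
    reference_gene: str,
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-sample expression ratios for every gene of interest in a Ct table.

    The table needs columns sample/gene/group/zt/ct (zt may be all-NaN).
    Technical replicates are first averaged on the Ct scale.  For each gene
    of interest, each sample's dCt uses the reference-gene Ct of the same
    sample, and ddCt subtracts the mean dCt of the gene in ``control_group``.

    Returns a frame with sample, gene, group, zt, dct, ddct, ratio.
    """
    _check_columns(table)
    avg = average_technical_replicates(table)
    ref = avg[avg["gene"] == reference_gene].set_index("sample")["ct"]
    if ref.empty:
        raise ValueError(f"no measurements of reference gene {reference_gene!r}")
    goi = avg[avg["gene"] != reference_gene].copy()
    missing_ref = sorted(set(goi["sample"]) - set(ref.index))
    if missing_ref:
        raise ValueError(f"samples without a reference-gene Ct: {missing_ref}")
    goi["dct"] = goi["ct"].to_numpy() - ref.reindex(goi["sample"]).to_numpy()
    out = []
    for gene, sub in goi.groupby("gene"):
        ctrl = sub.loc[sub["group"] == control_group, "dct"]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no control-group measurements")
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - ctrl.mean()
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    res["ratio"] = AMPLIFICATION ** (-res["ddct"])
    return res[["sample", "gene", "group", "zt", "dct", "ddct", "ratio"]]


def timepoint_profile(ratios: pd.DataFrame, gene: str | None = None) -> pd.DataFrame:
    """Per-ZT summary of expression ratios for one gene, flagging the baseline ZT.

    The baseline (the ZT whose mean ratio is lowest, ties going to the
    smallest ZT) is the within-curve comparison point for daily expression
    profiles.  Requires at least two distinct ZTs.

    Returns a frame indexed by zt with columns mean_ratio, sd_ratio, n and a
    boolean ``is_baseline`` (exactly one True row).
    """
    sub = ratios if gene is None else ratios[ratios["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no rows for gene {gene!r}")
    if sub["zt"].isna().any():
        raise ValueError("timepoint profiles need a ZT for every row")
    prof = (
        sub.groupby("zt")["ratio"]
        .agg(mean_ratio="mean", sd_ratio="std", n="size")
        .sort_index()
    )
    if len(prof) < 2:
        raise ValueError("need at least two Zeitgeber times for a profile")
    # ties resolved toward the earliest ZT: sort_index then idxmin takes the first minimum
    baseline = prof["mean_ratio"].idxmin()
    prof["is_baseline"] = prof.index == baseline
    return prof
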