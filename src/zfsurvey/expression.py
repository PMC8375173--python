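"""Expression-side computations: log2 TPM, expressed-gene filtering,
five-group hierarchical clustering, organ-level calls and 2^-ddCT qPCR.

The expected sample layout is the 15 wheat developmental stages spanning five
organs — roots (SR, RTLS, RMS), stems (S1S, STNS, SATS), leaves (SL, LTTS,
L2DAAs), spikes (SPTNS, SPMS, SPAS) and grains (G2DAAs, G14DAAs, G30DAAs) —
but arbitrary sample names are accepted everywhere except organ-level calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from zfsurvey.errors import ExpressionError

#: the 15 developmental stage codes in canonical order
STAGE_CODES = (
    "SR", "RTLS", "RMS",
    "S1S", "STNS", "SATS",
    "SL", "LTTS", "L2DAAs",
    "SPTNS", "SPMS", "SPAS",
    "G2DAAs", "G14DAAs", "G30DAAs",
)

#: stage code -> organ
STAGE_ORGANS: dict[str, str] = {
    "SR": "root", "RTLS": "root", "RMS": "root",
    "S1S": "stem", "STNS": "stem", "SATS": "stem",
    "SL": "leaf", "LTTS": "leaf", "L2DAAs": "leaf",
    "SPTNS": "spike", "SPMS": "spike", "SPAS": "spike",
    "G2DAAs": "grain", "G14DAAs": "grain", "G30DAAs": "grain",
}

ORGANS = ("root", "stem", "leaf", "spike", "grain")


@dataclass(frozen=True)
class GroupAssignment:
    """Gene -> expression group (1..k), groups ordered by ascending mean.

    ``groups`` maps gene id to group index; ``group_means`` holds the mean
    log2(TPM+1) of each group; ``sizes`` the member counts.
    """

    groups: pd.Series
    group_means: dict[int, float]
    sizes: dict[int, int]

    def members(self, group: int) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass(frozen=True)
class DdctResult:
    delta_ct_treated: float
    delta_ct_control: float
    ddct: float
    fold_change: float


def _check_matrix(matrix: pd.DataFrame) -> None:
    if (matrix.values < 0).any():
        raise ExpressionError("TPM matrix contains negative values")


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1); the pseudocount keeps zeros at zero."""
    _check_matrix(matrix)
    return np.log2(matrix + 1.0)


def expressed_filter(matrix: pd.DataFrame, min_tpm: float = 0.5,
                     min_samples: int = 1) -> pd.DataFrame:
    """Keep genes with TPM >= min_tpm in at least min_samples samples."""
    _check_matrix(matrix)
    keep = (matrix >= min_tpm).sum(axis=1) >= min_samples
    return matrix.loc[keep]


def cluster_groups(matrix: pd.DataFrame, k: int = 5) -> GroupAssignment:
    """Agglomerative clustering of log2(TPM+1) rows into k expression groups.

    Average linkage, Euclidean distance, cut to k clusters, then relabelled
    1..k by ascending cluster mean (ties broken by the first gene id in input
    order).  Deterministic given the input.
    """
    if len(matrix) < k:
        raise ExpressionError(f"cannot form {k} groups from {len(matrix)} genes")
    logm = log_transform(matrix)
    Z = linkage(logm.values, method="average", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    means: dict[int, float] = {}
    first_gene: dict[int, int] = {}
    for pos, label in enumerate(raw):
        if label not in first_gene:
            first_gene[label] = pos
    for label in set(raw):
        means[label] = float(logm.values[raw == label].mean())
    order = sorted(means, key=lambda l: (means[l], first_gene[l]))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    groups = pd.Series([relabel[l] for l in raw], index=matrix.index, name="group")
    return GroupAssignment(
        groups=groups,
        group_means={relabel[l]: means[l] for l in means},
        sizes={relabel[l]: int((raw == l).sum()) for l in means},
    )


def categorize_levels(log_matrix: pd.DataFrame, low_max: float = 1.0,
                      high_min: float = 5.0) -> pd.DataFrame:
    """Per-gene per-organ level calls on a log2-scale matrix.

    Columns must be known stage codes; each organ's level is the mean of its
    stages: low if <= low_max, high if >= high_min, else moderate.
    """
    unknown = [c for c in log_matrix.columns if c not in STAGE_ORGANS]
    if unknown:
        raise ExpressionError(f"unknown stage codes {unknown}; cannot map to organs")
    calls = {}
    for organ in ORGANS:
        cols = [c for c in log_matrix.columns if STAGE_ORGANS[c] == organ]
        if not cols:
            continue
        mean = log_matrix[cols].mean(axis=1)
        calls[organ] = np.where(mean <= low_max, "low",
                                np.where(mean >= high_min, "high", "moderate"))
    return pd.DataFrame(calls, index=log_matrix.index)


def fold_change_ddct(ct_target_treated: float, ct_ref_treated: float,
                     ct_target_control: float, ct_ref_control: float) -> DdctResult:
    """Relative quantification by the comparative 2^-ddCT method."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(v) or v <= 0:
            raise ExpressionError(f"CT values must be finite and positive, got {v}")
    d_t = ct_target_treated - ct_ref_treated
    d_c = ct_target_control - ct_ref_control
    ddct = d_t - d_c
    return DdctResult(
        delta_ct_treated=d_t, delta_ct_control=d_c,
        ddct=ddct, fold_change=float(2.0 ** (-ddct)),
    )


def read_tpm(path) -> pd.DataFrame:
    """Read a gene x sample TPM matrix from TSV (genes in rows, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_matrix(df)
    return df


def ddct_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Apply 2^-ddCT to a long CT table.

    Expects columns sample, gene, ct_target, ct_reference, condition with one
    ``control`` condition row per (sample, gene); every other condition is a
    treatment compared against it.
    """
    required = {"sample", "gene", "ct_target", "ct_reference", "condition"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ExpressionError(f"CT table lacks columns {sorted(missing)}")
    rows = []
    for (sample, gene), grp in ct_table.groupby(["sample", "gene"], sort=False):
        ctrl = grp[grp["condition"] == "control"]
        if len(ctrl) != 1:
            raise ExpressionError(
                f"({sample}, {gene}): expected exactly one control row, got {len(ctrl)}"
            )
        c = ctrl.iloc[0]
        for _, t in grp[grp["condition"] != "control"].iterrows():
            r = fold_change_ddct(t["ct_target"], t["ct_reference"],
                                 c["ct_target"], c["ct_reference"])
            rows.append({
                "sample": sample, "gene": gene, "condition": t["condition"],
                "ddct": r.ddct, "fold_change": r.fold_change,
            })
    return pd.DataFrame(rows, columns=["sample", "gene", "condition",
                                       "ddct", "fold_change"])
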