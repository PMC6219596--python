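"""qPCR ΔCT normalization and -ΔΔCT (log2 fold change) estimation.

Technical replicates are averaged per (sample, gene); ΔCT is the target
CT minus the geometric mean of two housekeeping reference CTs (taken on
the CT scale as stated; an arithmetic-mean switch is provided).  Per
gene, ΔCT is regressed on group, recording status and their
interaction; the negated group coefficient is the -ΔΔCT, equivalent to
a log2 fold change, with BH adjustment across the panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean
import statsmodels.formula.api as smf

from .enrichment import fdr_adjust

logger = logging.getLogger(__name__)

__all__ = ["CtPlate", "delta_ct", "log2fc_lm"]


@dataclass
class CtPlate:
    """Raw CT records plus per-sample metadata.

    ``records``: columns ``sample_id, gene, tech_rep, ct`` (CT > 0);
    ``meta``: columns ``sample_id, group, recorded``.
    """

    records: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"sample_id", "gene", "tech_rep", "ct"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"plate needs columns {sorted(req)}")
        if (self.records["ct"] <= 0).any():
            raise ValueError("CT values must be positive")
        req_meta = {"sample_id", "group", "recorded"}
        if not req_meta.issubset(self.meta.columns):
            raise ValueError(f"metadata needs columns {sorted(req_meta)}")


def delta_ct(
    plate: CtPlate,
    reference_genes: Sequence[str] = ("Gapdh", "Eif2ak1"),
    drop_targets: Sequence[str] = (),
    ref_mean: str = "geometric",
) -> pd.DataFrame:
    """ΔCT per (sample, target gene) against a two-gene reference.

    Technical replicates are averaged first; the reference value is the
    geometric mean (default; ``ref_mean="arithmetic"`` switches) of the
    two housekeeping genes' mean CTs.  Samples missing a reference gene
    are dropped with a warning; genes in ``drop_targets`` (e.g. poor
    amplification) are discarded.
    """
    if len(reference_genes) != 2:
        raise ValueError("exactly two reference genes are required")
    if ref_mean not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown ref_mean {ref_mean!r}")
    mean_ct = (
        plate.records.groupby(["sample_id", "gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
    )
    missing_ref = [g for g in reference_genes if g not in mean_ct.columns]
    if missing_ref:
        raise ValueError(f"reference genes absent from plate: {missing_ref}")

    has_refs = mean_ct[list(reference_genes)].notna().all(axis=1)
    if not has_refs.all():
        dropped = mean_ct.index[~has_refs].tolist()
        warnings.warn(f"samples missing a reference gene dropped: {dropped}",
                      stacklevel=2)
        mean_ct = mean_ct.loc[has_refs]

    refs = mean_ct[list(reference_genes)].to_numpy()
    ref_value = gmean(refs, axis=1) if ref_mean == "geometric" else refs.mean(axis=1)

    targets = [g for g in mean_ct.columns
               if g not in reference_genes and g not in set(drop_targets)]
    for g in set(drop_targets) & set(mean_ct.columns):
        logger.info("target %r discarded (flagged poor amplification)", g)
    out = mean_ct[targets].sub(pd.Series(ref_value, index=mean_ct.index), axis=0)
    return (
        out.stack()
        .rename("delta_ct")
        .reset_index()
        .rename(columns={"level_1": "gene"})
    )


def log2fc_lm(
    delta_cts: pd.DataFrame,
    meta: pd.DataFrame,
    case_label: str = "Pb",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-gene -ΔΔCT (log2 fold change) via OLS with a recording covariate.

    Model: delta_ct ~ group + recorded + group:recorded (treatment
    coding, control and not-recorded as references); when recording
    status does not vary it is omitted and the estimate reduces exactly
    to the difference of group mean ΔCTs.  Returns per-gene ``log2fc``
    (= -group coefficient), ``fold_change`` (2**log2fc), raw and
    BH-adjusted p.
    """
    df = delta_cts.merge(meta, on="sample_id", how="left")
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "sample_id"].unique().tolist()
        raise ValueError(f"samples without metadata: {missing}")
    df["is_case"] = (df["group"] == case_label).astype(float)
    df["is_recorded"] = (
        df["recorded"].astype(str).str.lower().isin(("yes", "true", "1"))
    ).astype(float)

    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        n_case = int(sub["is_case"].sum())
        n_ctrl = int((1 - sub["is_case"]).sum())
        if n_case < 2 or n_ctrl < 2:
            raise ValueError(f"gene {gene!r}: need >=2 samples per group "
                             f"(got {n_case} {case_label}, {n_ctrl} {control_label})")
        varying_rec = sub["is_recorded"].nunique() > 1
        formula = ("delta_ct ~ is_case * is_recorded" if varying_rec
                   else "delta_ct ~ is_case")
        model = smf.ols(formula, data=sub)
        if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
            aliased = [n for i, n in enumerate(model.exog_names)
                       if np.linalg.matrix_rank(np.delete(model.exog, i, axis=1))
                       == np.linalg.matrix_rank(model.exog)]
            raise ValueError(f"gene {gene!r}: rank-deficient design; aliased "
                             f"term(s): {aliased}")
        fit = model.fit()
        ddct = float(fit.params["is_case"])
        lo, hi = fit.conf_int().loc["is_case"]
        rows.append({
            "gene": gene,
            "log2fc": -ddct,
            "fold_change": 2.0 ** (-ddct),
            "se": float(fit.bse["is_case"]),
            # negation flips the interval ends
            "ci_low": -float(hi),
            "ci_high": -float(lo),
            "p": float(fit.pvalues["is_case"]),
            "n_case": n_case,
            "n_control": n_ctrl,
        })
    table = pd.DataFrame(rows)
    table["p_adj"] = fdr_adjust(np.clip(table["p"].to_numpy(), 1e-300, 1.0), "BH")
    return table
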