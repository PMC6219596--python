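"""Rank-based transcriptome signatures.

Expression matrices (genes-or-probes x samples) are rank-normalized per
sample ("RankNorm"): the highest expressed gene gets rank N, the lowest
rank 1, and all ranks are divided by N so values lie in (0, 1].  The
case/control difference of mean normalized ranks ("SubDiff") is a
per-gene differential expression value in [-1, +1].  Differentially
expressed genes are called by standardizing the SubDiff vector across
genes and thresholding the Z-score (default |Z| > 1.5), yielding a
directional signature (up/down gene lists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RankedProfile",
    "DifferentialProfile",
    "DirectionalSignature",
    "rank_normalize",
    "collapse_to_genes",
    "subdiff",
    "de_genes_by_z",
    "translate_genes",
]


@dataclass
class ExpressionMatrix:
    """Expression values (rows = genes or probes, columns = samples).

    ``groups`` optionally assigns each sample to ``"case"`` or
    ``"control"``; it is required only for differential operations.
    """

    data: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("empty expression matrix")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.data.index[r]!r} "
                f"in sample {self.data.columns[c]!r}"
            )
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            missing = [s for s in self.data.columns if s not in self.groups.index]
            if missing:
                raise ValueError(f"samples without a group label: {missing}")

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class RankedProfile:
    """Per-sample normalized ranks in (0, 1]; the max per sample is 1.0."""

    ranks: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.ranks.to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError("empty ranked profile")
        if (vals <= 0).any() or (vals > 1).any():
            raise ValueError("normalized ranks must lie in (0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.ranks.index


@dataclass
class DifferentialProfile:
    """Per-gene SubDiff values in [-1, +1] for one case/control contrast."""

    subdiff: pd.Series
    n_case: int = 1
    n_control: int = 1

    def __post_init__(self) -> None:
        self.subdiff = pd.Series(self.subdiff, dtype=float)
        if self.subdiff.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in profile")
        if (self.subdiff.abs() > 1 + 1e-12).any():
            raise ValueError("SubDiff values must lie in [-1, +1]")

    @property
    def genes(self) -> pd.Index:
        return self.subdiff.index

    def __len__(self) -> int:
        return len(self.subdiff)


@dataclass(frozen=True)
class DirectionalSignature:
    """Named gene lists split into up- and down-regulated members."""

    name: str
    up: frozenset = field(default_factory=frozenset)
    down: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if self.up & self.down:
            raise ValueError(
                f"signature {self.name!r}: up and down sets overlap "
                f"({sorted(self.up & self.down)[:5]} ...)"
            )
        if not self.up and not self.down:
            logger.warning("signature %r is empty on both sides", self.name)

    @property
    def one_sided(self) -> bool:
        return not (self.up and self.down)

    @property
    def all_genes(self) -> frozenset:
        return self.up | self.down


def rank_normalize(matrix: ExpressionMatrix | pd.DataFrame) -> RankedProfile:
    """Rank-normalize each sample to (0, 1].

    Per sample, the highest expression value receives rank N (= number
    of rows) and the lowest rank 1; ranks are then divided by N.  Ties
    receive the average of the tied integer ranks.
    """
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if data.shape[0] == 0 or data.shape[1] == 0:
        raise ValueError("empty expression matrix")
    vals = data.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        r, c = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite value for gene {data.index[r]!r} in sample {data.columns[c]!r}"
        )
    n = data.shape[0]
    # ascending average ranks: highest value -> N
    ranks = data.rank(axis=0, method="average") / n
    return RankedProfile(ranks=ranks)


def collapse_to_genes(
    matrix: ExpressionMatrix | pd.DataFrame,
    mapping: Mapping[str, str] | pd.Series,
    mode: str = "max_mean_intensity",
) -> ExpressionMatrix | RankedProfile:
    """Collapse probe-level rows to one row per gene.

    ``mode="max_mean_intensity"`` keeps, per gene, the probe with the
    highest mean intensity and returns an :class:`ExpressionMatrix`.
    ``mode="max_mean_rank"`` rank-normalizes first, keeps the probe with
    the highest mean normalized rank and returns a
    :class:`RankedProfile`.  Unmapped probes are dropped (count logged);
    criterion ties keep the first probe in input order.
    """
    groups = None
    if isinstance(matrix, ExpressionMatrix):
        groups = matrix.groups
        data = matrix.data
    else:
        data = matrix
    mapping = pd.Series(dict(mapping)) if not isinstance(mapping, pd.Series) else mapping
    if len(mapping) == 0:
        raise ValueError("empty probe-to-gene mapping")
    if mode not in ("max_mean_intensity", "max_mean_rank"):
        raise ValueError(f"unknown collapse mode {mode!r}")

    mapped = data.index.isin(mapping.index)
    n_dropped = int((~mapped).sum())
    if n_dropped:
        logger.info("collapse_to_genes: dropped %d unmapped probes", n_dropped)
    data = data.loc[mapped]
    if data.shape[0] == 0:
        raise ValueError("no probes map to a gene")

    if mode == "max_mean_rank":
        crit_source = rank_normalize(data).ranks
    else:
        crit_source = data
    crit = crit_source.mean(axis=1)
    genes = mapping.reindex(data.index)

    frame = pd.DataFrame({"gene": genes, "crit": crit}).reset_index(names="probe")
    # idxmax is stable: the first probe in input order wins criterion ties
    best = frame.loc[frame.groupby("gene", sort=False)["crit"].idxmax()]
    out = crit_source.loc[best["probe"]].copy() if mode == "max_mean_rank" else data.loc[best["probe"]].copy()
    out.index = pd.Index(best["gene"].to_numpy(), name="gene")
    if mode == "max_mean_rank":
        return RankedProfile(ranks=out)
    return ExpressionMatrix(data=out, groups=groups)


def subdiff(
    ranked: RankedProfile,
    groups: pd.Series | Mapping[str, str],
    case_label: str = "case",
    control_label: str = "control",
) -> DifferentialProfile:
    """Case-minus-control difference of mean normalized ranks, per gene.

    With one sample per group this is exactly the rank difference; with
    replicates, group means are differenced, which keeps the value in
    [-1, +1] and reduces to the single-sample rule at n = 1.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    case_cols = [s for s in ranked.ranks.columns if groups.get(s) == case_label]
    ctrl_cols = [s for s in ranked.ranks.columns if groups.get(s) == control_label]
    if not case_cols:
        raise ValueError(f"no samples labeled {case_label!r}")
    if not ctrl_cols:
        raise ValueError(f"no samples labeled {control_label!r}")
    diff = ranked.ranks[case_cols].mean(axis=1) - ranked.ranks[ctrl_cols].mean(axis=1)
    return DifferentialProfile(subdiff=diff, n_case=len(case_cols), n_control=len(ctrl_cols))


def de_genes_by_z(
    profile: DifferentialProfile,
    z_threshold: float = 1.5,
    name: str = "signature",
) -> DirectionalSignature:
    """Call DE genes by standardizing SubDiff across genes.

    Z = (subdiff - mean) / SD (sample SD across genes); ``up`` collects
    genes with Z > threshold, ``down`` genes with Z < -threshold.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if len(profile) < 3:
        raise ValueError("need at least 3 genes to standardize")
    vals = profile.subdiff
    sd = float(vals.std(ddof=1))
    # guard against all-equal profiles whose SD is only float-roundoff
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(vals.abs().max())):
        raise ValueError("degenerate profile: zero SubDiff variance")
    z = (vals - vals.mean()) / sd
    up = frozenset(z.index[z > z_threshold])
    down = frozenset(z.index[z < -z_threshold])
    return DirectionalSignature(name=name, up=up, down=down)


def translate_genes(
    genes: Iterable[str],
    mapping: Mapping[str, str] | pd.Series | None = None,
) -> frozenset:
    """Map gene identifiers through an optional two-column ortholog table.

    With ``mapping=None`` identifiers pass through unchanged (identity
    mapping); identifiers absent from a provided mapping are dropped.
    """
    if mapping is None:
        return frozenset(genes)
    mapping = dict(mapping) if not isinstance(mapping, pd.Series) else mapping.to_dict()
    return frozenset(mapping[g] for g in genes if g in mapping)
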