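"""Ocular dominance metrics and group comparisons.

Per neuron, the ocular dominance index (ODI) is computed from
baseline-subtracted peak firing rates evoked by each eye:

    ODI = (E_ipsi - E_contra) / (E_ipsi + E_contra),   E = peak - baseline

giving a value in [-1, +1] (-1 = completely contra-dominated).  ODI is
discretized to the 7-level ocular dominance score (ODS), and ODS counts
aggregate per animal into the contralateral bias index

    CBI = [(n1 - n7) + 2/3 (n2 - n6) + 1/3 (n3 - n5) + N] / (2 N)

in [0, 1] (higher = more contra-dominated).  Group comparisons: an
animal-level t test on CBI (optionally one-sided), a neuron-level
chi-squared test on the 7-bin ODS counts, a neuron-level two-sample KS
test on ODI, and a hierarchical linear model of neuron-level ODI with
group x experience fixed effects, a random intercept per animal, and
Holm-adjusted pairwise contrasts of the four cell means.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronResponse",
    "AnimalSummary",
    "UnresponsiveNeuron",
    "psth_summarize",
    "compute_odi",
    "odi_to_ods",
    "compute_cbi",
    "spont_evoked_ratio",
    "summarize_neurons",
    "summarize_animals",
    "group_compare",
    "hierarchical_model",
]


class UnresponsiveNeuron(ValueError):
    """Raised when a neuron's summed evoked response is nonpositive."""


@dataclass
class NeuronResponse:
    """Two-eye peak/baseline firing rates (spikes/s) for one neuron."""

    animal_id: str
    peak_ipsi: float
    base_ipsi: float
    peak_contra: float
    base_contra: float

    def __post_init__(self) -> None:
        for name in ("peak_ipsi", "base_ipsi", "peak_contra", "base_contra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def evoked_ipsi(self) -> float:
        return self.peak_ipsi - self.base_ipsi

    @property
    def evoked_contra(self) -> float:
        return self.peak_contra - self.base_contra


@dataclass
class AnimalSummary:
    """Animal-level ocular dominance summary."""

    animal_id: str
    group: str
    experience: str
    cbi: float
    n_neurons: int
    ods_counts: np.ndarray = field(default_factory=lambda: np.zeros(7, dtype=int))

    def __post_init__(self) -> None:
        self.ods_counts = np.asarray(self.ods_counts, dtype=int)
        if self.ods_counts.shape != (7,):
            raise ValueError("ods_counts must have 7 bins")
        if int(self.ods_counts.sum()) != self.n_neurons:
            raise ValueError("ods_counts must sum to n_neurons")
        if not 0.0 <= self.cbi <= 1.0:
            raise ValueError("CBI must lie in [0, 1]")


def psth_summarize(
    spike_times: np.ndarray,
    stimulus_onsets: np.ndarray,
    bin_ms: float = 25.0,
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0),
    response_window_ms: tuple[float, float] = (0.0, 500.0),
) -> tuple[float, float]:
    """Peak and baseline firing rate (spikes/s) from a peristimulus histogram.

    Spikes are binned relative to each stimulus onset (times in ms);
    baseline is the mean rate over the pre-stimulus window and peak the
    maximum trial-averaged binned rate in the response window.
    Returns ``(peak, baseline)``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    stimulus_onsets = np.asarray(stimulus_onsets, dtype=float)
    if stimulus_onsets.size == 0:
        raise ValueError("need at least one stimulus repetition")
    if spike_times.size == 0 and stimulus_onsets.size == 0:
        raise ValueError("no spikes and no stimuli")
    n_trials = stimulus_onsets.size
    rel = (spike_times[None, :] - stimulus_onsets[:, None]).ravel() if spike_times.size else np.array([])

    b0, b1 = baseline_window_ms
    r0, r1 = response_window_ms
    if not (b1 > b0 and r1 > r0 and bin_ms > 0):
        raise ValueError("windows must be nonempty and bin width positive")

    n_base = np.sum((rel >= b0) & (rel < b1)) if rel.size else 0
    baseline = n_base / n_trials / ((b1 - b0) / 1000.0)

    edges = np.arange(r0, r1 + bin_ms / 2, bin_ms)
    if rel.size:
        counts, _ = np.histogram(rel, bins=edges)
    else:
        counts = np.zeros(len(edges) - 1)
    rates = counts / n_trials / (bin_ms / 1000.0)
    peak = float(rates.max()) if rates.size else 0.0
    return peak, float(baseline)


def compute_odi(r: NeuronResponse) -> float:
    """Ocular dominance index from baseline-subtracted peak rates.

    Raises :class:`UnresponsiveNeuron` when the summed evoked response
    is nonpositive (the neuron is excluded from downstream counts).
    """
    e_ipsi = r.evoked_ipsi
    e_contra = r.evoked_contra
    denom = e_ipsi + e_contra
    if denom <= 0:
        raise UnresponsiveNeuron(
            f"neuron of animal {r.animal_id!r}: summed evoked response {denom} <= 0"
        )
    odi = (e_ipsi - e_contra) / denom
    # negative single-eye evoked rates can push the ratio outside [-1, 1]
    return float(np.clip(odi, -1.0, 1.0))


def odi_to_ods(odi: float) -> int:
    """Discretize ODI to the 7-level ocular dominance score.

    Bins: [-1.0, -0.5) -> 1, [-0.5, -0.3) -> 2, [-0.3, -0.1) -> 3,
    [-0.1, +0.1] -> 4, (+0.1, +0.3] -> 5, (+0.3, +0.5] -> 6,
    (+0.5, +1.0] -> 7 (note the closed center bin).
    """
    if not -1.0 <= odi <= 1.0:
        raise ValueError(f"ODI {odi} outside [-1, 1]")
    if odi < -0.5:
        return 1
    if odi < -0.3:
        return 2
    if odi < -0.1:
        return 3
    if odi <= 0.1:
        return 4
    if odi <= 0.3:
        return 5
    if odi <= 0.5:
        return 6
    return 7


def compute_cbi(ods_counts: np.ndarray) -> float:
    """Contralateral bias index from the 7-bin ODS counts."""
    counts = np.asarray(ods_counts, dtype=float)
    if counts.shape != (7,):
        raise ValueError("expected 7 ODS bins")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one neuron")
    n1, n2, n3, _, n5, n6, n7 = counts
    return float(((n1 - n7) + (2 / 3) * (n2 - n6) + (1 / 3) * (n3 - n5) + n) / (2 * n))


def spont_evoked_ratio(r: NeuronResponse) -> float:
    """Spontaneous-to-evoked firing rate ratio.

    Operationalized on the dominant eye (larger evoked response): the
    ratio of that eye's baseline rate to its peak rate.
    """
    if r.evoked_ipsi >= r.evoked_contra:
        peak, base = r.peak_ipsi, r.base_ipsi
    else:
        peak, base = r.peak_contra, r.base_contra
    if peak <= 0:
        raise UnresponsiveNeuron(
            f"neuron of animal {r.animal_id!r}: zero evoked rate"
        )
    return base / peak


def summarize_neurons(neurons: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-neuron ODI/ODS from a rate table; unresponsive neurons excluded.

    Expects columns ``animal_id, peak_ipsi, base_ipsi, peak_contra,
    base_contra`` (extra columns pass through).  Returns the annotated
    table and a QC dict with the exclusion count.
    """
    rows = []
    n_unresponsive = 0
    for _, row in neurons.iterrows():
        r = NeuronResponse(
            animal_id=str(row["animal_id"]),
            peak_ipsi=row["peak_ipsi"], base_ipsi=row["base_ipsi"],
            peak_contra=row["peak_contra"], base_contra=row["base_contra"],
        )
        try:
            odi = compute_odi(r)
        except UnresponsiveNeuron:
            n_unresponsive += 1
            continue
        out = dict(row)
        out["odi"] = odi
        out["ods"] = odi_to_ods(odi)
        rows.append(out)
    qc = {"n_input": len(neurons), "n_unresponsive": n_unresponsive,
          "n_kept": len(rows)}
    if n_unresponsive:
        logger.info("summarize_neurons: excluded %d unresponsive neurons", n_unresponsive)
    return pd.DataFrame(rows), qc


def _ods_counts(ods: pd.Series) -> np.ndarray:
    return np.bincount(ods.astype(int), minlength=8)[1:8]


def summarize_animals(
    neurons: pd.DataFrame,
    qc_min_cells: int = 0,
) -> list[AnimalSummary]:
    """Aggregate per-neuron ODS to animal-level CBI summaries.

    Animals with fewer than ``qc_min_cells`` responsive neurons are
    dropped (QC filter; default keeps all).
    """
    out = []
    for animal, sub in neurons.groupby("animal_id", sort=True):
        counts = _ods_counts(sub["ods"])
        if counts.sum() < max(qc_min_cells, 1):
            logger.info("animal %r dropped by QC (%d cells)", animal, counts.sum())
            continue
        out.append(AnimalSummary(
            animal_id=str(animal),
            group=str(sub["group"].iloc[0]) if "group" in sub else "",
            experience=str(sub["experience"].iloc[0]) if "experience" in sub else "",
            cbi=compute_cbi(counts),
            n_neurons=int(counts.sum()),
            ods_counts=counts,
        ))
    return out


def _chi2_ods(counts_a: np.ndarray, counts_b: np.ndarray) -> tuple[float, float]:
    """Chi-squared on a 2x7 ODS table; all-zero columns are dropped.

    Merging a zero-count bin into its neighbor toward the center bin is
    numerically identical to dropping it, so the table simply loses
    empty columns before testing.
    """
    table = np.vstack([counts_a, counts_b])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)


def group_compare(
    neurons: pd.DataFrame,
    group_a: str,
    group_b: str,
    group_col: str = "group",
    cbi_alternative: str = "two-sided",
    qc_min_cells: int = 0,
) -> dict:
    """Compare two groups of animals/neurons on ocular dominance.

    Emits an animal-level t test on CBI (``cbi_alternative`` in
    {"two-sided", "greater", "less"}, testing group_a vs group_b), a
    neuron-level chi-squared test on the 7-bin ODS counts, and a
    neuron-level two-sample KS test on ODI.
    """
    sub_a = neurons[neurons[group_col] == group_a]
    sub_b = neurons[neurons[group_col] == group_b]
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValueError("both groups need neurons")

    out: dict = {"group_a": group_a, "group_b": group_b}

    cbi_a = [a.cbi for a in summarize_animals(sub_a, qc_min_cells)]
    cbi_b = [a.cbi for a in summarize_animals(sub_b, qc_min_cells)]
    out["cbi_a"] = cbi_a
    out["cbi_b"] = cbi_b
    if len(cbi_a) >= 2 and len(cbi_b) >= 2:
        t = stats.ttest_ind(cbi_a, cbi_b, alternative=cbi_alternative)
        out["cbi_t"] = float(t.statistic)
        out["cbi_p"] = float(t.pvalue)
    else:
        warnings.warn("a group has fewer than 2 animals; CBI t test skipped",
                      stacklevel=2)
        out["cbi_t"] = out["cbi_p"] = float("nan")

    chi2, chi2_p = _chi2_ods(_ods_counts(sub_a["ods"]), _ods_counts(sub_b["ods"]))
    out["ods_chi2"] = chi2
    out["ods_chi2_p"] = chi2_p

    ks = stats.ks_2samp(sub_a["odi"], sub_b["odi"])
    out["odi_ks_D"] = float(ks.statistic)
    out["odi_ks_p"] = float(ks.pvalue)
    return out


def hierarchical_model(
    neurons: pd.DataFrame,
    outcome: str = "odi",
    group_col: str = "group",
    experience_col: str = "experience",
    animal_col: str = "animal_id",
) -> dict:
    """Linear mixed model of neuron-level ODI with a random intercept per animal.

    Group and experience enter as fixed effects through the four
    group x experience cell means (least-squares means under the
    random-intercept model); all pairwise cell contrasts are tested by
    Wald z tests and Holm-adjusted.  REML estimation; the numerical
    optimizer is statsmodels' MixedLM.  A singular fit is reported with
    ``singular=True`` and contrasts suppressed.
    """
    df = neurons[[outcome, group_col, experience_col, animal_col]].copy()
    df.columns = ["y", "group", "experience", "animal"]
    df["cell"] = df["group"].astype(str) + ":" + df["experience"].astype(str)
    cells = sorted(df["cell"].unique())
    for cell in cells:
        if df.loc[df["cell"] == cell, "animal"].nunique() < 2:
            warnings.warn(f"cell {cell!r} has fewer than 2 animals", stacklevel=2)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ 0 + C(cell)", df, groups=df["animal"])
            fit = model.fit(reml=True)
        fe = fit.fe_params
        cov = fit.cov_params().loc[fe.index, fe.index]
        if not np.isfinite(fe.to_numpy()).all() or not np.isfinite(np.diag(cov)).all():
            raise np.linalg.LinAlgError("non-finite fixed effects")
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("mixed model singular fit: %s", exc)
        return {"singular": True, "error": str(exc), "contrasts": None,
                "cell_means": None}

    name_of = {cell: f"C(cell)[{cell}]" for cell in cells}
    cell_means = {cell: float(fe[name_of[cell]]) for cell in cells}

    rows = []
    for a, b in itertools.combinations(cells, 2):
        contrast = np.zeros(len(fe))
        contrast[list(fe.index).index(name_of[a])] = 1.0
        contrast[list(fe.index).index(name_of[b])] = -1.0
        est = float(contrast @ fe.to_numpy())
        var = float(contrast @ cov.to_numpy() @ contrast)
        # a boundary fit can leave a non-PSD covariance; flag, don't crash
        se = float(np.sqrt(var)) if var > 0 and np.isfinite(var) else np.nan
        z = est / se if np.isfinite(se) else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se,
                     "z": z, "p": p,
                     "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se})
    contrasts = pd.DataFrame(rows)
    ok = np.isfinite(contrasts["p"].to_numpy())
    adj = np.full(len(contrasts), np.nan)
    if ok.any():
        adj[ok] = multipletests(contrasts["p"].to_numpy()[ok], method="holm")[1]
    contrasts["p_adj"] = adj
    return {
        "singular": False,
        "cell_means": cell_means,
        "animal_var": float(fit.cov_re.iloc[0, 0]),
        "resid_var": float(fit.scale),
        "contrasts": contrasts,
    }
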