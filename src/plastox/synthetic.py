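"""Synthetic data generators with planted ground truth.

Every stage of the screen has a download-free test surface: case/control
expression matrices with planted differentially expressed genes,
chemical-gene interaction tables with planted "reverser" chemicals
whose down-regulated genes overlap the plasticity signature's
up-regulated genes, four-cell (group x experience) electrophysiology
cohorts with planted ocular dominance shifts, and qPCR plates with
planted ΔΔCT effects.  Generators are byte-deterministic given the
configuration seed and each returns a machine-readable truth table.

Default cohort and effect sizes mirror the study conditions the
analyses target: 3/6/5/5 animals per cell with ~28.8 neurons per
animal, an MD-induced ODI shift of +0.28 of which lead-exposed animals
retain 57%, and qPCR ΔΔCT effects of +0.6 (Col18a1), +0.51 (Mbp) and
-0.92 (Il1b) at n = 8 exposed vs 6 control samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ephys import compute_odi, NeuronResponse
from .qpcr import CtPlate
from .signatures import DirectionalSignature, ExpressionMatrix
from .enrichment import ChemicalGeneTable

__all__ = [
    "SimConfig",
    "gen_expression",
    "gen_chem_table",
    "gen_cohort",
    "gen_qpcr",
    "gen_spikes",
]

# fixed per-generator stream tags so the four generators are independent
_TAG_EXPR, _TAG_CHEM, _TAG_COHORT, _TAG_QPCR, _TAG_SPIKES = 11, 13, 17, 19, 23


def _default_animals() -> dict:
    return {
        ("control", "noMD"): 3,
        ("control", "MD"): 6,
        ("Pb", "noMD"): 5,
        ("Pb", "MD"): 5,
    }


def _default_qpcr_effects() -> dict:
    # ΔΔCT on the CT scale; -ΔΔCT is the log2 fold change
    return {"Col18a1": 0.6, "Mbp": 0.51, "Il1b": -0.92, "Gad1": 0.0, "Pvalb": 0.0}


@dataclass
class SimConfig:
    """Knobs for all four generators; one seed drives every stream."""

    seed: int = 0

    # expression
    n_genes: int = 10_000
    n_case: int = 3
    n_control: int = 3
    n_de: int = 50
    de_effect: float = 4.0          # additive log2-intensity shift of planted genes
    gene_mean_log2: float = 8.0
    gene_sd_log2: float = 2.0
    noise_sd_log2: float = 0.5

    # chemical-gene table
    n_chemicals: int = 100
    set_size_range: tuple[int, int] = (10, 300)   # log-uniform per direction
    cp_up_size: int = 80
    cp_down_size: int = 80
    planted_reversers: tuple[tuple[str, float], ...] = ()
    reverser_n_down: int = 60
    reverser_n_up: int = 60

    # electrophysiology cohort
    animals_per_cell: Mapping[tuple[str, str], int] = field(default_factory=_default_animals)
    neurons_per_animal: float = 28.8
    baseline_odi: float = -0.2
    od_shift: float = 0.28
    pb_retention: float = 0.57      # fraction of the MD shift retained under Pb
    animal_sd: float = 0.05
    neuron_sd: float = 0.25
    evoked_sum: float = 10.0        # total evoked rate split between the eyes
    spont_mean: Mapping[str, float] = field(
        default_factory=lambda: {"control": 2.0, "Pb": 3.0})

    # qPCR
    qpcr_effects: Mapping[str, float] = field(default_factory=_default_qpcr_effects)
    qpcr_n_case: int = 8
    qpcr_n_control: int = 6
    qpcr_ref_ct: float = 20.0
    qpcr_ref_sd: float = 0.2
    qpcr_noise_sd: float = 0.2
    qpcr_tech_sd: float = 0.05
    qpcr_n_tech: int = 3

    def __post_init__(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be at least 100")
        for _, frac in self.planted_reversers:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("overlap fractions must lie in [0, 1]")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, tag])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def gen_expression(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log-normal case/control intensities with planted DE genes.

    ``n_de`` planted genes receive an additive log2 shift of
    ``de_effect`` in case samples (alternating up/down).  Planted genes
    are drawn from the central 90% of baseline intensity: a rank-based
    caller cannot, by construction, register an upward shift of a gene
    already at the top rank, so planting in the saturated tails would
    put unrecoverable entries in the truth table.  Returns the matrix
    and a truth table of planted genes and directions.
    """
    rng = _rng(config, _TAG_EXPR)
    genes = _gene_ids(config.n_genes)
    base = rng.normal(config.gene_mean_log2, config.gene_sd_log2, config.n_genes)
    n_samples = config.n_case + config.n_control
    log2_vals = base[:, None] + rng.normal(0.0, config.noise_sd_log2,
                                           (config.n_genes, n_samples))
    lo, hi = np.quantile(base, [0.05, 0.95])
    central = np.flatnonzero((base > lo) & (base < hi))
    de_idx = rng.choice(central, config.n_de, replace=False) if config.n_de else np.array([], dtype=int)
    directions = np.array(["up", "down"])[np.arange(config.n_de) % 2]
    shift = np.where(directions == "up", config.de_effect, -config.de_effect)
    log2_vals[de_idx, : config.n_case] += shift[:, None]

    samples = [f"case_{i}" for i in range(config.n_case)] + [
        f"control_{i}" for i in range(config.n_control)]
    groups = pd.Series(["case"] * config.n_case + ["control"] * config.n_control,
                       index=samples)
    data = pd.DataFrame(2.0 ** log2_vals, index=pd.Index(genes, name="gene"),
                        columns=samples)
    truth = pd.DataFrame({"gene": [genes[i] for i in de_idx], "direction": directions})
    return ExpressionMatrix(data=data, groups=groups), truth


def gen_chem_table(
    config: SimConfig,
) -> tuple[ChemicalGeneTable, DirectionalSignature, frozenset, pd.DataFrame]:
    """Chemical-gene interaction records with planted reverser chemicals.

    Decoy chemicals draw up/down genes uniformly from the universe (set
    sizes log-uniform within ``set_size_range`` per direction).  Each
    planted reverser draws ``overlap_fraction`` of its down genes from
    the plasticity up-signature.  Returns the table, the plasticity
    signature, the universe genes, and the truth table.
    """
    rng = _rng(config, _TAG_CHEM)
    genes = np.array(_gene_ids(config.n_genes))
    cp_idx = rng.choice(config.n_genes, config.cp_up_size + config.cp_down_size,
                        replace=False)
    cp_up = frozenset(genes[cp_idx[: config.cp_up_size]])
    cp_down = frozenset(genes[cp_idx[config.cp_up_size:]])
    cp = DirectionalSignature(name="CP", up=cp_up, down=cp_down)
    cp_up_arr = np.array(sorted(cp_up))

    lo, hi = config.set_size_range
    records = []
    for i in range(config.n_chemicals):
        name = f"chem_{i:03d}"
        for direction in ("increased", "decreased"):
            size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            for g in genes[rng.choice(config.n_genes, size, replace=False)]:
                records.append((name, g, direction))

    planted = []
    for name, frac in config.planted_reversers:
        n_overlap = int(round(frac * config.reverser_n_down))
        down = set(cp_up_arr[rng.choice(len(cp_up_arr), n_overlap, replace=False)])
        pool = np.array(sorted(set(genes) - cp_up))
        down |= set(pool[rng.choice(len(pool), config.reverser_n_down - n_overlap,
                                    replace=False)])
        up = set(genes[rng.choice(config.n_genes, config.reverser_n_up, replace=False)])
        for g in sorted(down):
            records.append((name, g, "decreased"))
        for g in sorted(up):
            records.append((name, g, "increased"))
        planted.append({"chemical": name, "overlap_fraction": frac,
                        "n_down": config.reverser_n_down,
                        "n_overlap_planted": n_overlap})

    table = ChemicalGeneTable(records=pd.DataFrame(
        records, columns=["chemical", "gene", "direction"]))
    truth = pd.DataFrame(planted, columns=["chemical", "overlap_fraction",
                                           "n_down", "n_overlap_planted"])
    return table, cp, frozenset(genes), truth


def _cell_mean(config: SimConfig, group: str, experience: str) -> float:
    mean = config.baseline_odi
    if experience == "MD":
        shift = config.od_shift
        if group == "Pb":
            shift *= config.pb_retention
        mean += shift
    return mean


def gen_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Four-cell electrophysiology cohort with planted ODI shifts.

    Neuron ODIs are truncated-normal around a per-animal mean
    (animal-level SD around the cell mean); evoked rates are
    back-computed so :func:`plastox.ephys.compute_odi` round-trips the
    planted ODI exactly.  Returns the neuron table and a truth table of
    cell means.
    """
    rng = _rng(config, _TAG_COHORT)
    rows = []
    truth_rows = []
    for (group, experience), n_animals in sorted(config.animals_per_cell.items()):
        mu_cell = _cell_mean(config, group, experience)
        truth_rows.append({"group": group, "experience": experience,
                           "odi_mean": mu_cell, "n_animals": n_animals})
        for a in range(n_animals):
            animal = f"{group}_{experience}_{a}"
            mu_animal = mu_cell + rng.normal(0.0, config.animal_sd)
            n_neurons = max(10, int(rng.poisson(config.neurons_per_animal)))
            lo = (-1.0 - mu_animal) / config.neuron_sd
            hi = (1.0 - mu_animal) / config.neuron_sd
            odis = stats.truncnorm.rvs(lo, hi, loc=mu_animal,
                                       scale=config.neuron_sd,
                                       size=n_neurons, random_state=rng)
            spont = rng.gamma(4.0, config.spont_mean[group] / 4.0, n_neurons)
            for odi, base in zip(odis, spont):
                evoked_ipsi = (1.0 + odi) * config.evoked_sum / 2.0
                evoked_contra = (1.0 - odi) * config.evoked_sum / 2.0
                rows.append({
                    "animal_id": animal, "group": group, "experience": experience,
                    "peak_ipsi": base + evoked_ipsi, "base_ipsi": base,
                    "peak_contra": base + evoked_contra, "base_contra": base,
                    "odi_true": float(odi),
                })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def gen_spikes(
    response: NeuronResponse,
    n_trials: int = 20,
    rng: np.random.Generator | None = None,
    trial_spacing_ms: float = 2000.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Poisson spike trains consistent with a neuron's rate summary.

    Per eye, spikes are emitted at the baseline rate through each trial
    and at the peak rate inside the [0, 500) ms response window.
    Returns eye -> (spike_times_ms, stimulus_onsets_ms).
    """
    rng = rng or np.random.default_rng(0)
    out = {}
    for eye, peak, base in (("ipsi", response.peak_ipsi, response.base_ipsi),
                            ("contra", response.peak_contra, response.base_contra)):
        onsets = np.arange(n_trials) * trial_spacing_ms + 1000.0
        spikes = []
        for onset in onsets:
            for t0, t1, rate in ((-500.0, 0.0, base), (0.0, 500.0, peak)):
                n = rng.poisson(rate * (t1 - t0) / 1000.0)
                spikes.append(onset + rng.uniform(t0, t1, n))
        out[eye] = (np.sort(np.concatenate(spikes)), onsets)
    return out


def gen_qpcr(config: SimConfig) -> tuple[CtPlate, pd.DataFrame]:
    """CT plate with two reference genes and planted per-gene ΔΔCT effects.

    Reference CTs ~ N(ref_ct, ref_sd^2); target CT = reference geometric
    mean + per-gene baseline ΔCT + group ΔΔCT + biological noise, with
    ``qpcr_n_tech`` technical replicates per well.  Recording status is
    assigned within both groups so the covariate is estimable.
    """
    rng = _rng(config, _TAG_QPCR)
    genes = sorted(config.qpcr_effects)
    base_dct = {g: rng.normal(4.0, 1.0) for g in genes}

    samples, meta_rows = [], []
    for group, n in (("Pb", config.qpcr_n_case), ("control", config.qpcr_n_control)):
        for i in range(n):
            sid = f"{group}_{i}"
            # roughly half of each group was recorded from before dissection
            recorded = "yes" if i < (n + 1) // 2 else "no"
            samples.append((sid, group))
            meta_rows.append({"sample_id": sid, "group": group, "recorded": recorded})

    records = []
    for sid, group in samples:
        ref_cts = {
            "Gapdh": rng.normal(config.qpcr_ref_ct, config.qpcr_ref_sd),
            "Eif2ak1": rng.normal(config.qpcr_ref_ct, config.qpcr_ref_sd),
        }
        ref_gmean = float(stats.gmean(list(ref_cts.values())))
        for gene, ct in ref_cts.items():
            for rep in range(1, config.qpcr_n_tech + 1):
                records.append({"sample_id": sid, "gene": gene, "tech_rep": rep,
                                "ct": ct + rng.normal(0.0, config.qpcr_tech_sd)})
        for gene in genes:
            effect = config.qpcr_effects[gene] if group == "Pb" else 0.0
            ct = (ref_gmean + base_dct[gene] + effect
                  + rng.normal(0.0, config.qpcr_noise_sd))
            for rep in range(1, config.qpcr_n_tech + 1):
                records.append({"sample_id": sid, "gene": gene, "tech_rep": rep,
                                "ct": ct + rng.normal(0.0, config.qpcr_tech_sd)})

    plate = CtPlate(records=pd.DataFrame(records), meta=pd.DataFrame(meta_rows))
    truth = pd.DataFrame({
        "gene": genes,
        "ddct": [config.qpcr_effects[g] for g in genes],
        "log2fc": [-config.qpcr_effects[g] for g in genes],
    })
    return plate, truth
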