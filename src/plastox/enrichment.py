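"""Gene-set libraries and hypergeometric overlap screening.

Chemical gene-set libraries are built from chemical-gene interaction
records (chemical, gene, direction in {increased, decreased}), filtered
by set size (default 3-2500 genes).  Overlaps against a directional
plasticity signature are scored with upper-tail hypergeometric tests on
a custom background universe (the intersection of the assay
transcriptome and all chemically-annotated genes), with
Benjamini-Hochberg adjustment.  The directional "reversal" screen tests
chemical down-genes against signature up-genes and vice versa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signatures import DirectionalSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ChemicalGeneTable",
    "GeneSetLibrary",
    "Universe",
    "EnrichmentResult",
    "build_universe",
    "build_composite_library",
    "split_library",
    "hypergeom_overlap",
    "reversal_screen",
    "fisher_overlap",
    "fisher_overlap_counts",
    "library_enrichment",
    "fdr_adjust",
]

DIRECTIONS = ("increased", "decreased")

RESULT_COLUMNS = [
    "set_a", "set_b", "k", "size_a", "size_b", "N",
    "odds_ratio", "p", "p_adj", "rank",
]


@dataclass
class ChemicalGeneTable:
    """Deduplicated (chemical, gene, direction) interaction records."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chemical", "gene", "direction"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"interaction table needs columns {sorted(req)}")
        bad = set(self.records["direction"]) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"invalid direction values: {sorted(bad)}")
        self.records = self.records.drop_duplicates(
            subset=["chemical", "gene", "direction"]
        ).reset_index(drop=True)

    @property
    def chemicals(self) -> list[str]:
        return sorted(self.records["chemical"].unique())

    @property
    def genes(self) -> frozenset:
        return frozenset(self.records["gene"])

    def genes_for(self, chemical: str, direction: str | None = None) -> frozenset:
        rec = self.records[self.records["chemical"] == chemical]
        if direction is not None:
            rec = rec[rec["direction"] == direction]
        return frozenset(rec["gene"])


@dataclass
class GeneSetLibrary:
    """Named gene sets, every one inside the [min_size, max_size] bounds."""

    sets: dict = field(default_factory=dict)
    min_size: int = 3
    max_size: int = 2500

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        for name, members in self.sets.items():
            if not (self.min_size <= len(members) <= self.max_size):
                raise ValueError(
                    f"set {name!r} has {len(members)} genes, outside "
                    f"[{self.min_size}, {self.max_size}]"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


@dataclass(frozen=True)
class Universe:
    """Background gene population for enrichment 2x2 tables."""

    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError("empty universe")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """One overlap test: counts, sample odds ratio, raw/adjusted p."""

    set_a: str
    set_b: str
    k: int
    size_a: int
    size_b: int
    N: int
    odds_ratio: float
    p: float
    p_adj: float = float("nan")
    rank: int | None = None

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in RESULT_COLUMNS}


def _overlap_cells(k: int, size_a: int, size_b: int, n: int) -> tuple[int, int, int, int]:
    b = size_a - k
    c = size_b - k
    d = n - size_a - size_b + k
    if min(b, c, d) < 0:
        raise ValueError(f"inconsistent 2x2 table: k={k}, |A|={size_a}, |B|={size_b}, N={n}")
    return k, b, c, d


def _sample_odds_ratio(k: int, size_a: int, size_b: int, n: int) -> float:
    k, b, c, d = _overlap_cells(k, size_a, size_b, n)
    if b * c == 0:
        return math.inf if k * d > 0 else math.nan
    return (k * d) / (b * c)


def _restrict(genes: Iterable[str], universe: Universe, label: str) -> frozenset:
    genes = frozenset(genes)
    inside = genes & universe.genes
    dropped = len(genes) - len(inside)
    if dropped:
        logger.info("%s: dropped %d genes outside the universe", label, dropped)
    return inside


def build_universe(transcriptome_genes: Iterable[str], chem_table: ChemicalGeneTable) -> Universe:
    """Background = transcriptome genes also annotated to some chemical."""
    transcriptome = frozenset(transcriptome_genes)
    if not transcriptome:
        raise ValueError("empty transcriptome gene set")
    chem_genes = chem_table.genes
    inter = transcriptome & chem_genes
    logger.info(
        "universe: transcriptome=%d, chemical genes=%d, intersection=%d",
        len(transcriptome), len(chem_genes), len(inter),
    )
    if not inter:
        raise ValueError("transcriptome and chemical gene sets are disjoint")
    return Universe(genes=inter)


def build_composite_library(
    chem_table: ChemicalGeneTable,
    neurotoxicant_filter: Sequence[str] | None = None,
    min_size: int = 3,
    max_size: int = 2500,
) -> GeneSetLibrary:
    """One composite set per chemical: union of its increased and decreased genes.

    ``neurotoxicant_filter`` restricts to named chemicals
    (case-insensitive exact match); sets outside [min_size, max_size]
    are dropped with a logged count.
    """
    chems = chem_table.chemicals
    if neurotoxicant_filter is not None:
        wanted = {c.lower() for c in neurotoxicant_filter}
        chems = [c for c in chems if c.lower() in wanted]
    sets = {}
    n_dropped = 0
    for chem in chems:
        members = chem_table.genes_for(chem)
        if min_size <= len(members) <= max_size:
            sets[chem] = members
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("composite library: %d chemicals dropped by size filter", n_dropped)
    return GeneSetLibrary(sets=sets, min_size=min_size, max_size=max_size)


def split_library(
    chem_table: ChemicalGeneTable,
    chemicals: Sequence[str],
    min_size: int = 3,
    max_size: int = 2500,
) -> tuple[GeneSetLibrary, GeneSetLibrary]:
    """Split retained chemicals into up/down libraries, re-filtered by size.

    A chemical whose up (resp. down) set falls outside the bounds after
    splitting is absent from that library; it may survive in one only.
    """
    up_sets, down_sets = {}, {}
    for chem in chemicals:
        up = chem_table.genes_for(chem, "increased")
        down = chem_table.genes_for(chem, "decreased")
        if min_size <= len(up) <= max_size:
            up_sets[chem] = up
        if min_size <= len(down) <= max_size:
            down_sets[chem] = down
    logger.info(
        "split library: %d chemicals -> %d up sets, %d down sets",
        len(chemicals), len(up_sets), len(down_sets),
    )
    return (
        GeneSetLibrary(sets=up_sets, min_size=min_size, max_size=max_size),
        GeneSetLibrary(sets=down_sets, min_size=min_size, max_size=max_size),
    )


def hypergeom_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Universe,
    name_a: str = "A",
    name_b: str = "B",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= k) for the overlap of A and B.

    Population N = |universe|, successes |A|, draws |B|; genes outside
    the universe are dropped before counting.  The odds ratio is the
    sample OR of the 2x2 table.
    """
    a = _restrict(set_a, universe, name_a)
    b = _restrict(set_b, universe, name_b)
    if not a or not b:
        raise ValueError("empty gene set after restriction to the universe")
    n = len(universe)
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, n, len(a), len(b)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(
        set_a=name_a, set_b=name_b, k=k, size_a=len(a), size_b=len(b), N=n,
        odds_ratio=_sample_odds_ratio(k, len(a), len(b), n), p=p,
    )


def fisher_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Universe,
    name_a: str = "A",
    name_b: str = "B",
) -> EnrichmentResult:
    """Two-sided Fisher exact test on the overlap 2x2 table."""
    a = _restrict(set_a, universe, name_a)
    b = _restrict(set_b, universe, name_b)
    if not a or not b:
        raise ValueError("empty gene set after restriction to the universe")
    res = fisher_overlap_counts(len(a & b), len(a), len(b), len(universe))
    res.set_a, res.set_b = name_a, name_b
    return res


def fisher_overlap_counts(k: int, size_a: int, size_b: int, n: int) -> EnrichmentResult:
    """Fisher test built directly from the four overlap counts."""
    k, b, c, d = _overlap_cells(k, size_a, size_b, n)
    if min(size_a, size_b) == 0 or size_a == n or size_b == n:
        raise ValueError("degenerate 2x2 table: a zero marginal")
    _, p = stats.fisher_exact([[k, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        set_a="A", set_b="B", k=k, size_a=size_a, size_b=size_b, N=n,
        odds_ratio=_sample_odds_ratio(k, size_a, size_b, n), p=float(p),
    )


def fdr_adjust(p_values: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up (default) or Holm step-down."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    key = {"BH": "fdr_bh", "holm": "holm"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def _screen_table(results: list[EnrichmentResult], alpha: float) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(columns=RESULT_COLUMNS + ["significant"])
    table = pd.DataFrame([r.to_dict() for r in results])
    table["p_adj"] = fdr_adjust(table["p"].to_numpy(), "BH")
    table = table.sort_values(["p_adj", "set_a"], kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["significant"] = table["p_adj"] < alpha
    return table


def reversal_screen(
    tox_up: GeneSetLibrary,
    tox_down: GeneSetLibrary,
    cp: DirectionalSignature,
    universe: Universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Directional reversal screen: chemical-down vs signature-up and vice versa.

    Both test families are pooled into one BH family; rows are ranked by
    adjusted p, ties broken alphabetically by chemical name.
    """
    if not tox_up.sets and not tox_down.sets:
        raise ValueError("both chemical libraries are empty")
    cp_up = _restrict(cp.up, universe, f"{cp.name}_up")
    cp_down = _restrict(cp.down, universe, f"{cp.name}_down")
    results: list[EnrichmentResult] = []
    if cp_up:
        for chem, members in sorted(tox_down.sets.items()):
            res = hypergeom_overlap(members, cp_up, universe, chem, f"{cp.name}_up")
            res.set_b = f"{cp.name}_up"
            results.append(res)
    else:
        logger.info("reversal screen: empty up-signature, family skipped")
    if cp_down:
        for chem, members in sorted(tox_up.sets.items()):
            results.append(hypergeom_overlap(members, cp_down, universe, chem, f"{cp.name}_down"))
    else:
        logger.info("reversal screen: empty down-signature, family skipped")
    return _screen_table(results, alpha)


def composite_screen(
    library: GeneSetLibrary,
    signature_genes: Iterable[str],
    universe: Universe,
    signature_name: str = "signature",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Non-directional screen of every composite set against the signature."""
    if not library.sets:
        raise ValueError("empty library")
    sig = _restrict(signature_genes, universe, signature_name)
    if not sig:
        raise ValueError("signature empty after restriction to the universe")
    results = [
        hypergeom_overlap(members, sig, universe, chem, signature_name)
        for chem, members in sorted(library.sets.items())
    ]
    return _screen_table(results, alpha)


def library_enrichment(
    shared_genes: Iterable[str],
    library: GeneSetLibrary,
    universe: Universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list against every library set.

    One test per set, BH-adjusted within the library.  Sets that are
    empty after restriction to the universe score p = 1.
    """
    if not library.sets:
        raise ValueError("empty library")
    shared = _restrict(shared_genes, universe, "shared")
    results = []
    for name, members in sorted(library.sets.items()):
        inside = members & universe.genes
        if not inside or not shared:
            results.append(EnrichmentResult(
                set_a=name, set_b="shared", k=0, size_a=len(inside),
                size_b=len(shared), N=len(universe),
                odds_ratio=math.nan, p=1.0,
            ))
            continue
        results.append(hypergeom_overlap(inside, shared, universe, name, "shared"))
    return _screen_table(results, alpha)


__all__.append("composite_screen")
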