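"""Readers and writers for the plain-text formats the pipeline uses.

Expression matrices, sample groups, chemical-gene interaction records,
neuron rate tables and qPCR plates travel as TSV; gene-set libraries
and directional signatures travel as GMT (name, description, members,
tab-separated; directional signatures emit "_up"/"_down" suffixed
rows).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .enrichment import ChemicalGeneTable, GeneSetLibrary
from .qpcr import CtPlate
from .signatures import DirectionalSignature, ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_groups_tsv",
    "read_gmt",
    "write_gmt",
    "write_signature_gmt",
    "read_signature_gmt",
    "read_chem_table_tsv",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_neuron_tsv",
    "read_plate_tsv",
]


def read_expression_tsv(path: str | Path, groups_path: str | Path | None = None) -> ExpressionMatrix:
    """Expression TSV: first column gene/probe id, remaining columns samples."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    groups = read_groups_tsv(groups_path) if groups_path is not None else None
    return ExpressionMatrix(data=data, groups=groups)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_groups_tsv(path: str | Path) -> pd.Series:
    """Two-column sample -> group TSV (header ``sample<TAB>group``)."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def read_gmt(path: str | Path) -> dict:
    """GMT: per line ``name<TAB>description<TAB>member...``."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, frozenset], path: str | Path,
              description: str = "plastox") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_signature_gmt(signature: DirectionalSignature, path: str | Path) -> None:
    write_gmt(
        {f"{signature.name}_up": signature.up, f"{signature.name}_down": signature.down},
        path,
    )


def read_signature_gmt(path: str | Path, name: str | None = None) -> DirectionalSignature:
    """Rebuild a directional signature from ``<name>_up`` / ``<name>_down`` rows."""
    sets = read_gmt(path)
    ups = {k[:-3]: v for k, v in sets.items() if k.endswith("_up")}
    downs = {k[:-5]: v for k, v in sets.items() if k.endswith("_down")}
    names = sorted(set(ups) | set(downs))
    if name is None:
        if len(names) != 1:
            raise ValueError(f"ambiguous signature GMT; names found: {names}")
        name = names[0]
    return DirectionalSignature(
        name=name, up=ups.get(name, frozenset()), down=downs.get(name, frozenset())
    )


def library_to_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    write_gmt(library.sets, path)


def read_chem_table_tsv(path: str | Path) -> ChemicalGeneTable:
    """Interaction TSV with header ``chemical<TAB>gene<TAB>direction``."""
    return ChemicalGeneTable(records=pd.read_csv(path, sep="\t"))


def read_profile_tsv(path: str | Path) -> pd.Series:
    """Differential profile TSV with header ``gene<TAB>subdiff``."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=df.iloc[:, 0].astype(str), name="subdiff")


def write_profile_tsv(profile: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"gene": profile.index, "subdiff": profile.to_numpy()}).to_csv(
        path, sep="\t", index=False)


def read_neuron_tsv(path: str | Path) -> pd.DataFrame:
    """Neuron rate table: animal_id, group, experience, peak/base per eye."""
    df = pd.read_csv(path, sep="\t")
    required = {"animal_id", "peak_ipsi", "base_ipsi", "peak_contra", "base_contra"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"neuron table missing columns: {sorted(missing)}")
    return df


def read_plate_tsv(plate_path: str | Path, meta_path: str | Path) -> CtPlate:
    """qPCR plate + metadata TSVs (see :class:`plastox.qpcr.CtPlate`)."""
    return CtPlate(records=pd.read_csv(plate_path, sep="\t"),
                   meta=pd.read_csv(meta_path, sep="\t"))


__all__.append("library_to_gmt")
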