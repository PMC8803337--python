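"""Readers and writers for every external file format the pipeline touches.

Formats
-------
* DE tables: tab-separated UTF-8 with a header row; column names configurable,
  defaults ``gene / log2fc / pvalue / fdr`` (``fdr`` optional).
* Gene sets: standard GMT (set name, description, then members, tab-separated).
* Ortholog maps: two tab-separated columns, optional header.
* TF-target collections: three tab-separated columns (TF, target, mode) in the
  TRRUST dialect; the regulation mode is carried into the set description but
  not otherwise used.
* Results: tab-separated table plus a JSON sidecar recording parameters, seed
  and row counts.  Output is byte-identical for identical inputs; floats are
  printed with 12 significant digits.

Parsers never silently drop rows: a rejected row is counted and reported.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    DETable,
    GeneSet,
    GeneSetCollection,
    OrthologMap,
    Species,
    ValidationError,
)

__all__ = [
    "DEFAULT_DE_COLUMNS",
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_trrust",
    "write_results",
    "FLOAT_FORMAT",
]

DEFAULT_DE_COLUMNS: dict[str, str] = {
    "gene": "gene",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "fdr": "fdr",
}

#: 12 significant digits: round-trips through text within the documented
#: precision contract.
FLOAT_FORMAT = "%.12g"


def read_de_table(
    path: str | Path,
    label: str,
    species: Species | str = Species.synthetic,
    columns: Mapping[str, str] | None = None,
) -> DETable:
    """Read a differential-expression table from tab-separated text.

    Rows with an empty gene identifier or non-numeric log2fc/pvalue are
    rejected and reported on the returned table's ``rejected`` attribute
    (columns ``row``, ``gene``, ``reason``); accepted + rejected row counts
    always add up to the input row count.  A duplicated gene identifier or a
    p-value outside [0, 1] is an error, not a rejection.

    When the fdr column is absent the table is returned with ``fdr`` unset on
    all records and ``needs_bh`` True.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such DE table: {path}")
    cols = dict(DEFAULT_DE_COLUMNS)
    if columns:
        cols.update(columns)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key in ("gene", "log2fc", "pvalue"):
        if cols[key] not in raw.columns:
            raise ValidationError(
                f"{path}: missing mandatory column '{cols[key]}' "
                f"(have {list(raw.columns)})"
            )
    gene = raw[cols["gene"]].astype(str).str.strip()
    lfc = pd.to_numeric(raw[cols["log2fc"]], errors="coerce")
    pv = pd.to_numeric(raw[cols["pvalue"]], errors="coerce")
    has_fdr = cols["fdr"] in raw.columns
    fdr = pd.to_numeric(raw[cols["fdr"]], errors="coerce") if has_fdr else None

    reasons = pd.Series("", index=raw.index, dtype=object)
    reasons[gene.str.len() == 0] = "empty gene"
    reasons[(reasons == "") & (~np.isfinite(lfc))] = "non-numeric log2fc"
    reasons[(reasons == "") & pv.isna()] = "non-numeric pvalue"
    keep = reasons == ""

    rejected = pd.DataFrame(
        {"row": raw.index[~keep] + 2,  # 1-based file line, after the header
         "gene": gene[~keep], "reason": reasons[~keep]}
    ).reset_index(drop=True)

    data = pd.DataFrame({"gene": gene[keep], "log2fc": lfc[keep], "pvalue": pv[keep]})
    if has_fdr:
        data["fdr"] = fdr[keep]
    table = DETable(data.reset_index(drop=True), label=label, species=species)
    table.rejected = rejected
    return table


def write_de_table(table: DETable, path: str | Path) -> None:
    """Write a DETable as tab-separated text (fdr column omitted when unset)."""
    df = table.data
    if not table.has_fdr:
        df = df.drop(columns=["fdr"])
    _write_tsv(df, Path(path))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: one set per line, ``name<TAB>desc<TAB>members...``.

    Members are deduplicated and empty member fields dropped.  A line with
    fewer than three fields or a duplicated set name is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such GMT file: {path}")
    sets: dict[str, GeneSet] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name '{name}'")
            sets[name] = GeneSet(name, desc, members)
    if not sets:
        raise ValidationError(f"{path}: GMT file contains no sets")
    return GeneSetCollection(sets, source_label=path.name)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a GeneSetCollection as GMT; members sorted for determinism."""
    lines = []
    for name in sorted(collection.names()):
        gs = collection[name]
        lines.append("\t".join([gs.name, gs.description, *sorted(gs.members)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_HEADER_TOKENS = {
    "gene_a", "gene_b", "a", "b", "mouse", "human", "source", "target",
    "symbol_a", "symbol_b", "ortholog",
}


def read_ortholog_map(
    path: str | Path,
    a_species: Species | str = Species.mouse,
    b_species: Species | str = Species.human,
) -> OrthologMap:
    """Read a two-column tab-separated ortholog map (optional header row).

    A first line whose fields both look like column labels (``gene_a``,
    ``mouse``, ``human``, ...) is treated as a header.  Multiplicity is
    allowed (one-to-many recorded as repeated gene_a or gene_b); an exactly
    duplicated pair or a malformed line is an error.  One-to-one / one-to-many
    / many-to-one counts are available via ``multiplicity_counts()``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such ortholog map: {path}")
    pairs: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValidationError(
                    f"{path}:{lineno}: expected two non-empty tab-separated fields"
                )
            if lineno == 1 and all(f.lower() in _HEADER_TOKENS for f in fields):
                continue
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValidationError(f"{path}: empty ortholog map")
    return OrthologMap(pairs, a_species, b_species)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    lines = ["gene_a\tgene_b"] + [f"{a}\t{b}" for a, b in omap.pairs]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trrust(path: str | Path) -> GeneSetCollection:
    """Read TF→target interactions (TRRUST dialect) into one set per TF.

    Three tab-separated columns: TF, target, regulation mode.  Targets are
    deduplicated per TF; the distribution of modes is recorded in the set
    description but does not affect any downstream test.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TF-target file: {path}")
    targets: dict[str, set[str]] = {}
    modes: dict[str, dict[str, int]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            tf, target, mode = fields[0], fields[1], fields[2]
            if not tf or not target:
                raise ValidationError(f"{path}:{lineno}: empty TF or target")
            targets.setdefault(tf, set()).add(target)
            modes.setdefault(tf, {})
            modes[tf][mode] = modes[tf].get(mode, 0) + 1
    if not targets:
        raise ValidationError(f"{path}: no TF-target interactions")
    sets = {
        tf: GeneSet(
            tf,
            ";".join(f"{m}={c}" for m, c in sorted(modes[tf].items())),
            frozenset(tg),
        )
        for tf, tg in targets.items()
    }
    return GeneSetCollection(sets, source_label=path.name)


def _results_to_frame(results: Any) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results.copy()
    results = list(results)
    if results and dataclasses.is_dataclass(results[0]):
        rows = []
        for r in results:
            row = {}
            for f in dataclasses.fields(r):
                v = getattr(r, f.name)
                if isinstance(v, (str, int, float, bool, np.integer, np.floating)) \
                        or v is None:
                    row[f.name] = v
            rows.append(row)
        return pd.DataFrame(rows)
    return pd.DataFrame(results)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def write_results(
    results: Any,
    path: str | Path,
    parameters: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a result collection as a tab-separated table plus a JSON sidecar.

    ``results`` may be a DataFrame, a list of result dataclasses (scalar
    fields are exported) or a list of mappings.  The sidecar
    ``<path>.run.json`` records parameters, seed, row/column counts.  Output
    bytes are identical for identical inputs and parameters.

    Returns the sidecar path.
    """
    df = _results_to_frame(results)
    if len(df) == 0:
        raise ValidationError("refusing to write an empty result collection")
    path = Path(path)
    _write_tsv(df, path)
    sidecar = path.with_name(path.name + ".run.json")
    summary = {
        "table": path.name,
        "n_rows": int(len(df)),
        "columns": list(map(str, df.columns)),
        "parameters": dict(parameters or {}),
        "seed": seed,
    }
    sidecar.write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    return sidecar
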