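"""In-memory domain types shared across the pipeline.

Every module downstream of I/O operates on these validated containers, never
on raw files or bare DataFrames.  Validation is eager: a constructed object is
guaranteed to satisfy its invariants (unique gene identifiers, probabilities in
[0, 1], disjoint up/down sets, ...), so downstream code does not re-check.

Gene identifiers are case-sensitive strings throughout.  No automatic
mouse/human case conversion is ever applied; cross-species mapping always goes
through an explicit :class:`OrthologMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Species",
    "DETable",
    "GeneSet",
    "GeneSetCollection",
    "OrthologMap",
    "Signature",
    "RankedVector",
    "PairedVector",
    "ValidationError",
]


class ValidationError(ValueError):
    """An object violated a domain-type invariant."""


class Species(str, Enum):
    mouse = "mouse"
    human = "human"
    synthetic = "synthetic"


DE_COLUMNS = ("gene", "log2fc", "pvalue", "fdr")


@dataclass
class DETable:
    """A differential-expression result table: one row per gene.

    Parameters
    ----------
    data
        DataFrame with columns ``gene`` (unique, non-empty strings),
        ``log2fc`` (finite floats, log2 units), ``pvalue`` (in [0, 1]) and
        ``fdr`` (in [0, 1], or NaN when the source table carried no adjusted
        p-values — run :func:`sigcross.signatures.add_fdr` before
        thresholding in that case).
    label
        Human-readable identifier of the contrast, e.g. ``"KO_E18.5_ds1"``.
    species
        Species of the gene identifiers.
    rejected
        Optional per-row report of input rows the parser rejected
        (columns ``row``, ``reason``).  Not part of the table's value.
    """

    data: pd.DataFrame
    label: str
    species: Species = Species.synthetic
    rejected: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        df = self.data
        missing = [c for c in ("gene", "log2fc", "pvalue") if c not in df.columns]
        if missing:
            raise ValidationError(f"DETable missing mandatory column(s): {missing}")
        if "fdr" not in df.columns:
            df = df.assign(fdr=np.nan)
        df = df.loc[:, list(DE_COLUMNS)].reset_index(drop=True)
        if len(df) == 0:
            raise ValidationError("DETable must contain at least one record")
        genes = df["gene"].astype(str)
        if (genes.str.len() == 0).any():
            raise ValidationError("DETable contains an empty gene identifier")
        dup = genes[genes.duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate gene identifier(s) in '{self.label}': "
                f"{sorted(set(dup))[:5]}"
            )
        lfc = pd.to_numeric(df["log2fc"], errors="coerce")
        if not np.isfinite(lfc).all():
            bad = df["gene"][~np.isfinite(lfc)].tolist()[:5]
            raise ValidationError(f"non-finite log2fc for gene(s) {bad}")
        pv = pd.to_numeric(df["pvalue"], errors="coerce")
        if pv.isna().any() or (pv < 0).any() or (pv > 1).any():
            bad = df["gene"][~pv.between(0, 1)].tolist()[:5]
            raise ValidationError(f"pvalue outside [0, 1] for gene(s) {bad}")
        fdr = pd.to_numeric(df["fdr"], errors="coerce")
        present = fdr.notna()
        if ((fdr[present] < 0) | (fdr[present] > 1)).any():
            raise ValidationError("fdr outside [0, 1]")
        self.data = pd.DataFrame(
            {"gene": genes, "log2fc": lfc.astype(float),
             "pvalue": pv.astype(float), "fdr": fdr.astype(float)}
        )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene"])

    @property
    def has_fdr(self) -> bool:
        """True when every record carries an adjusted p-value."""
        return bool(self.data["fdr"].notna().all())

    @property
    def needs_bh(self) -> bool:
        """True when the table was read without an fdr column."""
        return not self.has_fdr

    def log2fc_by_gene(self) -> pd.Series:
        return self.data.set_index("gene")["log2fc"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if not self.members:
            raise ValidationError(f"gene set '{self.name}' is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, deduplicated members."""

    sets: dict[str, GeneSet]
    source_label: str = ""

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"set key '{name}' != set name '{gs.name}'")

    @classmethod
    def from_dict(
        cls,
        sets: Mapping[str, Iterable[str]],
        source_label: str = "",
        descriptions: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        descriptions = descriptions or {}
        out: dict[str, GeneSet] = {}
        for name, members in sets.items():
            out[name] = GeneSet(name, descriptions.get(name, ""), frozenset(members))
        return cls(out, source_label)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for gs in self:
            out |= gs.members
        return out


@dataclass
class OrthologMap:
    """Cross-species gene pairings; one-to-many recorded as multiple pairs."""

    pairs: list[tuple[str, str]]
    a_species: Species = Species.mouse
    b_species: Species = Species.human

    def __post_init__(self) -> None:
        self.a_species = Species(self.a_species)
        self.b_species = Species(self.b_species)
        if not self.pairs:
            raise ValidationError("OrthologMap must contain at least one pair")
        seen: set[tuple[str, str]] = set()
        for pair in self.pairs:
            if pair in seen:
                raise ValidationError(f"duplicate ortholog pair {pair}")
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return out

    def b_to_a(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(b, set()).add(a)
        return out

    def one_to_one(self) -> dict[str, str]:
        """Pairs whose mapping is unique in both directions."""
        fwd, rev = self.a_to_b(), self.b_to_a()
        return {
            a: next(iter(bs))
            for a, bs in fwd.items()
            if len(bs) == 1 and len(rev[next(iter(bs))]) == 1
        }

    def multiplicity_counts(self) -> dict[str, int]:
        fwd, rev = self.a_to_b(), self.b_to_a()
        one_to_many = sum(1 for bs in fwd.values() if len(bs) > 1)
        many_to_one = sum(1 for as_ in rev.values() if len(as_) > 1)
        return {
            "n_pairs": len(self.pairs),
            "one_to_one": len(self.one_to_one()),
            "one_to_many": one_to_many,
            "many_to_one": many_to_one,
        }

    def inverted(self) -> "OrthologMap":
        return OrthologMap(
            [(b, a) for a, b in self.pairs], self.b_species, self.a_species
        )


@dataclass
class Signature:
    """Discrete up/down gene sets passing fdr <= fdr_max and |log2fc| >= lfc_min."""

    up: frozenset[str]
    down: frozenset[str]
    fdr_max: float
    lfc_min: float
    source_label: str = ""

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        overlap = self.up & self.down
        if overlap:
            raise ValidationError(f"up/down overlap: {sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class RankedVector:
    """A full, strictly ordered ranking of genes by log2 fold change.

    Ties in log2fc are broken by gene identifier (ascending lexicographic) so
    the ordering is deterministic across platforms.
    """

    genes: tuple[str, ...]
    values: tuple[float, ...]
    order: str = "descending"  # or "ascending"

    def __post_init__(self) -> None:
        if self.order not in ("descending", "ascending"):
            raise ValidationError(f"unknown order '{self.order}'")
        if len(self.genes) != len(self.values):
            raise ValidationError("genes and values length mismatch")
        if len(self.genes) == 0:
            raise ValidationError("RankedVector must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene in RankedVector")
        sign = -1.0 if self.order == "descending" else 1.0
        keys = [(sign * v, g) for g, v in zip(self.genes, self.values)]
        if keys != sorted(keys):
            raise ValidationError("RankedVector is not sorted per its order")

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self) -> dict[str, int]:
        """1-based rank of every gene."""
        return {g: i + 1 for i, g in enumerate(self.genes)}


@dataclass
class PairedVector:
    """Fold changes over strict one-to-one ortholog pairs present in both tables.

    ``dropped`` accounts for every candidate gene of table A that did not make
    it into a pair, by reason: ``unmapped`` (absent from the ortholog map),
    ``ambiguous`` (not one-to-one), ``missing_in_b`` (partner not measured in
    table B).
    """

    data: pd.DataFrame  # columns gene_a, gene_b, fc_a, fc_b, ordered by gene_a
    dropped: dict[str, int]
    label_a: str = ""
    label_b: str = ""

    def __post_init__(self) -> None:
        need = ["gene_a", "gene_b", "fc_a", "fc_b"]
        if list(self.data.columns) != need:
            self.data = self.data.loc[:, need]
        if self.data["gene_a"].duplicated().any():
            raise ValidationError("gene_a appears twice in PairedVector")
        if self.data["gene_b"].duplicated().any():
            raise ValidationError("gene_b appears twice in PairedVector")

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    def fc_a(self) -> np.ndarray:
        return self.data["fc_a"].to_numpy()

    def fc_b(self) -> np.ndarray:
        return self.data["fc_b"].to_numpy()

    def swapped(self) -> "PairedVector":
        df = self.data.rename(
            columns={"gene_a": "gene_b", "gene_b": "gene_a",
                     "fc_a": "fc_b", "fc_b": "fc_a"}
        )
        df = df.loc[:, ["gene_a", "gene_b", "fc_a", "fc_b"]]
        df = df.sort_values("gene_a", kind="mergesort").reset_index(drop=True)
        return PairedVector(df, dict(self.dropped), self.label_b, self.label_a)
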