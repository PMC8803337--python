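"""Cross-species mapping of gene sets and fold-change vectors.

Mapping always goes through an explicit :class:`~sigcross.datatypes.OrthologMap`;
there is no implicit symbol-case fallback.  The default policy is
``strict_one_to_one``: a gene participates only when its mapping is unique in
both directions, which avoids double counting in downstream enrichment
universes (the alternative ``expand_all`` includes every mapped partner).
Every candidate gene is accounted for: kept + dropped-by-reason counts always
add up exactly.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import DETable, OrthologMap, PairedVector, Species, ValidationError

__all__ = [
    "map_gene_set",
    "pair_fold_changes",
    "uppercase_identity_map",
    "MapReport",
]


class MapReport(dict):
    """Dropped genes by reason: mapping of reason -> sorted gene list."""

    def counts(self) -> dict[str, int]:
        return {reason: len(genes) for reason, genes in self.items()}


def map_gene_set(
    genes: set[str],
    omap: OrthologMap,
    policy: str = "strict_one_to_one",
) -> tuple[set[str], MapReport]:
    """Map a gene set from species A to species B.

    ``strict_one_to_one`` keeps only genes whose mapping is unique in both
    directions; ``expand_all`` includes every mapped partner of every gene.
    Returns the mapped set and a report of dropped genes by reason
    (``unmapped`` always; ``ambiguous`` under the strict policy).
    """
    if policy not in ("strict_one_to_one", "expand_all"):
        raise ValidationError(f"unknown ortholog policy '{policy}'")
    fwd = omap.a_to_b()
    report = MapReport(unmapped=[], ambiguous=[])
    mapped: set[str] = set()
    if policy == "strict_one_to_one":
        one2one = omap.one_to_one()
        for g in sorted(genes):
            if g not in fwd:
                report["unmapped"].append(g)
            elif g in one2one:
                mapped.add(one2one[g])
            else:
                report["ambiguous"].append(g)
    else:
        for g in sorted(genes):
            if g not in fwd:
                report["unmapped"].append(g)
            else:
                mapped |= fwd[g]
    return mapped, report


def pair_fold_changes(
    table_a: DETable, table_b: DETable, omap: OrthologMap
) -> PairedVector:
    """Build the paired fold-change vector over strict one-to-one orthologs.

    One entry per one-to-one ortholog pair measured in both tables, ordered by
    gene_a.  Candidates are all genes of table A; the dropped counts
    (``unmapped``, ``ambiguous``, ``missing_in_b``) plus n_pairs equal
    len(table_a) exactly.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValidationError("both DE tables must be non-empty")
    fwd = omap.a_to_b()
    one2one = omap.one_to_one()
    fc_a = table_a.log2fc_by_gene()
    fc_b = table_b.log2fc_by_gene()
    dropped = {"unmapped": 0, "ambiguous": 0, "missing_in_b": 0}
    rows = []
    for a in sorted(fc_a.index):
        if a not in fwd:
            dropped["unmapped"] += 1
        elif a not in one2one:
            dropped["ambiguous"] += 1
        elif one2one[a] not in fc_b.index:
            dropped["missing_in_b"] += 1
        else:
            b = one2one[a]
            rows.append((a, b, float(fc_a[a]), float(fc_b[b])))
    if not rows:
        raise ValidationError(
            f"no ortholog pairs shared by '{table_a.label}' and '{table_b.label}'"
        )
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "fc_a", "fc_b"])
    return PairedVector(df, dropped, label_a=table_a.label, label_b=table_b.label)


def uppercase_identity_map(
    genes: set[str],
    a_species: Species | str = Species.mouse,
    b_species: Species | str = Species.human,
) -> OrthologMap:
    """Build an explicit map sending each symbol to its uppercase form.

    A convenience for mouse-to-human comparisons when no curated map is
    available; constructing it is a deliberate, visible act, never a fallback
    applied silently.
    """
    pairs = sorted((g, g.upper()) for g in genes)
    return OrthologMap(pairs, a_species, b_species)
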