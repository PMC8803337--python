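"""Synthetic paired two-species DE studies with planted transcriptional programs.

The generator plants latent "programs" — blocks of genes sharing a common
true log2 fold change — inside a background of null genes, then observes each
gene through a normal sampling model:

* per program k, an effect delta_k is drawn once from
  Normal(effect, effect_sd^2) and signed per the program's direction
  (``mixed`` flips the sign per member gene);
* per gene g, the true effect beta_g sums the effects of the programs it
  belongs to; non-members have beta_g = 0 exactly;
* the observed log2fc is Normal(beta_g, tau^2) with sampling standard error
  tau = residual_sd * sqrt(2 / n_replicates_per_group), i.e. the standard
  error of a difference of two group means of per-replicate log2 expression;
* the p-value is the two-sided normal tail of log2fc / tau and the fdr column
  is its Benjamini-Hochberg adjustment.

A study pair shares the programs flagged shared — identical true effects,
independent observation noise — and is linked by a partially complete
ortholog map (species-B symbols are the uppercase of species-A symbols; a
configurable fraction of genes is left unmapped, and a fraction of mapped
genes is made ambiguous).  Reference gene sets tag each program imperfectly
through a sensitivity (membership recall) and precision (fraction of set
members that are true members), with size-matched decoy sets as negative
controls.  Every statistic downstream therefore has known ground truth.

All randomness flows from the single seed in the config, through one
generator stream, in documented order: program effects, species-A noise,
species-B effects/noise, ortholog-map construction, reference sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DETable,
    GeneSet,
    GeneSetCollection,
    OrthologMap,
    Species,
    ValidationError,
)
from .signatures import bh_adjust

__all__ = [
    "ProgramSpec",
    "GenerativeConfig",
    "SyntheticStudyPair",
    "simulate_de_study",
    "simulate_pair",
    "simulate_reference_sets",
    "simulate_comparison_bank",
    "random_gene_sets",
    "gene_names",
]

_UNMAPPED_SUFFIX = "x"  # appended to species-B symbols of unmapped genes
_ALT_SUFFIX = "ALT"  # bogus extra partner symbol for ambiguous entries


@dataclass(frozen=True)
class ProgramSpec:
    """One planted program: a block of genes with a shared true effect."""

    name: str
    size: int
    effect: float
    effect_sd: float = 0.0
    direction: str = "up"  # up | down | mixed

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError(f"program '{self.name}': size must be >= 1")
        if self.effect_sd < 0:
            raise ValidationError(f"program '{self.name}': effect_sd must be >= 0")
        if self.direction not in ("up", "down", "mixed"):
            raise ValidationError(
                f"program '{self.name}': unknown direction '{self.direction}'"
            )
        if self.direction == "up" and self.effect <= 0:
            raise ValidationError(
                f"program '{self.name}': direction=up requires effect > 0"
            )


@dataclass
class GenerativeConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a mid-sized two-group RNA-Seq contrast: 2000 genes, one
    up-regulated program of 100 genes with a true log2FC of 2, per-replicate
    log2 expression noise of 1, and 4 replicates per group (so the fold-change
    standard error is sqrt(2/4) ~ 0.707); 90% ortholog coverage with no
    ambiguous mappings; reference sets with 0.8 sensitivity and precision.
    """

    n_genes: int = 2000
    programs: list[ProgramSpec] = field(
        default_factory=lambda: [ProgramSpec("program1", 100, 2.0)]
    )
    program_membership_overlap: float = 0.0
    n_replicates_per_group: int = 4
    residual_sd: float = 1.0
    ortholog_coverage: float = 0.9
    one_to_many_fraction: float = 0.0
    refset_sensitivity: float = 0.8
    refset_precision: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if sum(p.size for p in self.programs) > self.n_genes:
            raise ValidationError("sum of program sizes exceeds n_genes")
        if not 0 <= self.program_membership_overlap < 1:
            raise ValidationError("program_membership_overlap must lie in [0, 1)")
        if self.n_replicates_per_group < 2:
            raise ValidationError("n_replicates_per_group must be >= 2")
        if self.residual_sd <= 0:
            raise ValidationError("residual_sd must be positive")
        if not 0 < self.ortholog_coverage <= 1:
            raise ValidationError("ortholog_coverage must lie in (0, 1]")
        if not 0 <= self.one_to_many_fraction < 1:
            raise ValidationError("one_to_many_fraction must lie in [0, 1)")
        for name, v in (("refset_sensitivity", self.refset_sensitivity),
                        ("refset_precision", self.refset_precision)):
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must lie in (0, 1]")
        names = [p.name for p in self.programs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate program names")

    @property
    def tau(self) -> float:
        """Sampling standard error of an observed log2 fold change."""
        return self.residual_sd * np.sqrt(2.0 / self.n_replicates_per_group)


@dataclass
class SyntheticStudyPair:
    """Two linked synthetic studies with full ground truth."""

    table_a: DETable
    table_b: DETable
    truth: pd.DataFrame  # indexed by species-A gene
    ortholog_map: OrthologMap
    reference_sets: GeneSetCollection
    shared_programs: tuple[str, ...]


def gene_names(n_genes: int) -> list[str]:
    """Species-A gene symbols g00000, g00001, ..."""
    return [f"g{i:05d}" for i in range(n_genes)]


def _membership(config: GenerativeConfig) -> dict[str, np.ndarray]:
    """Gene indices of each program: contiguous blocks, optionally overlapping
    the previous program by floor(overlap * size) genes."""
    out: dict[str, np.ndarray] = {}
    start = 0
    prev_end = 0
    for prog in config.programs:
        shift = int(np.floor(config.program_membership_overlap * prog.size))
        start = max(prev_end - shift, 0)
        end = start + prog.size
        if end > config.n_genes:
            raise ValidationError(
                f"program '{prog.name}' does not fit into n_genes with the "
                "requested overlap"
            )
        out[prog.name] = np.arange(start, end)
        prev_end = end
    return out


def _draw_effects(
    config: GenerativeConfig,
    membership: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-program member-gene effect vectors: delta_k drawn once per program,
    signed per direction (per-gene sign for ``mixed``)."""
    effects: dict[str, np.ndarray] = {}
    for prog in config.programs:
        delta = float(rng.normal(prog.effect, prog.effect_sd))
        members = membership[prog.name]
        if prog.direction == "down":
            vec = np.full(members.size, -delta)
        elif prog.direction == "mixed":
            signs = rng.choice([-1.0, 1.0], size=members.size)
            vec = signs * delta
        else:
            vec = np.full(members.size, delta)
        effects[prog.name] = vec
    return effects


def _beta(
    config: GenerativeConfig,
    membership: dict[str, np.ndarray],
    effects: dict[str, np.ndarray],
) -> np.ndarray:
    beta = np.zeros(config.n_genes)
    for name, idx in membership.items():
        beta[idx] += effects[name]
    return beta


def _observe(
    config: GenerativeConfig,
    beta: np.ndarray,
    genes: list[str],
    label: str,
    species: Species,
    rng: np.random.Generator,
) -> DETable:
    tau = config.tau
    lfc = rng.normal(beta, tau)
    p = 2.0 * stats.norm.sf(np.abs(lfc) / tau)
    p = np.minimum(p, 1.0)
    data = pd.DataFrame(
        {"gene": genes, "log2fc": lfc, "pvalue": p, "fdr": bh_adjust(p)}
    )
    return DETable(data, label=label, species=species)


def _truth_frame(
    config: GenerativeConfig,
    membership: dict[str, np.ndarray],
    beta: np.ndarray,
    genes: list[str],
) -> pd.DataFrame:
    programs = [[] for _ in range(config.n_genes)]
    for name, idx in membership.items():
        for i in idx:
            programs[i].append(name)
    return pd.DataFrame(
        {
            "beta": beta,
            "programs": [";".join(p) for p in programs],
            "is_member": [bool(p) for p in programs],
        },
        index=pd.Index(genes, name="gene"),
    )


def simulate_de_study(
    config: GenerativeConfig,
    label: str = "synthetic_study",
    species: Species = Species.synthetic,
    effects: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DETable, pd.DataFrame]:
    """Simulate one DE study; returns the observed table and the truth frame.

    ``effects`` allows reusing pre-drawn program effects (how a pair shares a
    program); when omitted, effects are drawn from the stream.  Deterministic
    given the config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    membership = _membership(config)
    if effects is None:
        effects = _draw_effects(config, membership, rng)
    beta = _beta(config, membership, effects)
    genes = gene_names(config.n_genes)
    table = _observe(config, beta, genes, label, species, rng)
    truth = _truth_frame(config, membership, beta, genes)
    return table, truth


def _species_b_symbols(
    genes: list[str], mapped: np.ndarray
) -> tuple[list[str], list[tuple[str, str]]]:
    """Uppercase species-B symbols; unmapped genes get a distinguishing suffix
    so that nothing pairs without the explicit map."""
    mapped_set = set(int(i) for i in mapped)
    symbols = [
        g.upper() if i in mapped_set else g.upper() + _UNMAPPED_SUFFIX
        for i, g in enumerate(genes)
    ]
    pairs = [(genes[i], symbols[i]) for i in sorted(mapped_set)]
    return symbols, pairs


def simulate_pair(
    config: GenerativeConfig,
    shared_programs: list[str] | None = None,
) -> SyntheticStudyPair:
    """Simulate a linked two-species study pair.

    Programs in ``shared_programs`` (default: all) have identical true
    effects in both studies; the rest exist in species A only, so an
    unshared pair is a genuine null for cross-species correlation.  The
    ortholog map covers ``ortholog_coverage`` of the genes exactly
    (count rounded), with ``one_to_many_fraction`` of the mapped genes made
    ambiguous by a bogus extra partner.  Reference sets are built on
    species-A symbols from the species-A truth.
    """
    program_names = [p.name for p in config.programs]
    if shared_programs is None:
        shared_programs = list(program_names)
    unknown = set(shared_programs) - set(program_names)
    if unknown:
        raise ValidationError(f"unknown shared program(s): {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    membership = _membership(config)
    genes_a = gene_names(config.n_genes)

    effects_a = _draw_effects(config, membership, rng)
    beta_a = _beta(config, membership, effects_a)
    table_a = _observe(config, beta_a, genes_a, "synthetic_species_a",
                       Species.synthetic, rng)

    # Non-shared programs are absent from species B entirely: giving them
    # independently re-drawn effects on the same member genes would still
    # correlate the two species (the product of two draws centered on the
    # same nonzero effect has nonzero mean), which is not a null.
    shared_membership = {name: membership[name] for name in shared_programs}
    effects_b = {name: effects_a[name] for name in shared_programs}
    beta_b = _beta(config, shared_membership, effects_b)

    n_mapped = int(round(config.ortholog_coverage * config.n_genes))
    n_mapped = max(n_mapped, 1)
    mapped = np.sort(rng.choice(config.n_genes, size=n_mapped, replace=False))
    symbols_b, pairs = _species_b_symbols(genes_a, mapped)
    n_ambig = int(round(config.one_to_many_fraction * n_mapped))
    if n_ambig:
        ambig = np.sort(rng.choice(mapped, size=n_ambig, replace=False))
        pairs = pairs + [
            (genes_a[i], genes_a[i].upper() + _ALT_SUFFIX) for i in ambig
        ]
    omap = OrthologMap(sorted(pairs), Species.synthetic, Species.synthetic)

    table_b = _observe(config, beta_b, symbols_b, "synthetic_species_b",
                       Species.synthetic, rng)

    truth = _truth_frame(config, membership, beta_a, genes_a)
    truth["beta_b"] = beta_b
    truth = truth.rename(columns={"beta": "beta_a"})
    truth["gene_b"] = symbols_b
    shared_member = np.zeros(config.n_genes, dtype=bool)
    for name in shared_programs:
        shared_member[membership[name]] = True
    truth["shared_member"] = shared_member

    reference_sets = simulate_reference_sets(
        truth.rename(columns={"beta_a": "beta"}),
        sensitivity=config.refset_sensitivity,
        precision=config.refset_precision,
        rng=rng,
    )
    return SyntheticStudyPair(
        table_a=table_a,
        table_b=table_b,
        truth=truth,
        ortholog_map=omap,
        reference_sets=reference_sets,
        shared_programs=tuple(shared_programs),
    )


def simulate_reference_sets(
    truth: pd.DataFrame,
    sensitivity: float,
    precision: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_decoys_per_program: int = 1,
) -> GeneSetCollection:
    """Reference sets that tag each planted program imperfectly.

    Each program's set includes every true member with probability
    ``sensitivity`` and is padded with uniformly drawn non-members so that the
    expected fraction of true members equals ``precision``.  For each program,
    ``n_decoys_per_program`` size-matched decoy sets are drawn uniformly from
    the non-program genes.
    """
    for name, v in (("sensitivity", sensitivity), ("precision", precision)):
        if not 0 < v <= 1:
            raise ValidationError(f"{name} must lie in (0, 1]")
    if len(truth) == 0:
        raise ValidationError("truth frame is empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    genes = np.asarray(truth.index)
    program_members: dict[str, list[str]] = {}
    for gene, progs in truth["programs"].items():
        if progs:
            for name in progs.split(";"):
                program_members.setdefault(name, []).append(gene)
    sets: dict[str, GeneSet] = {}
    for name in sorted(program_members):
        members = np.asarray(program_members[name])
        if sensitivity >= 1.0:
            included = members
        else:
            keep = rng.random(members.size) < sensitivity
            included = members[keep]
            if included.size == 0:  # degenerate draw: keep the set non-empty
                included = members[:1]
        nonmembers = genes[~np.isin(genes, members)]
        n_pad = int(round(sensitivity * members.size * (1.0 - precision) / precision))
        n_pad = min(n_pad, nonmembers.size)
        pad = (
            rng.choice(nonmembers, size=n_pad, replace=False)
            if n_pad
            else np.array([], dtype=genes.dtype)
        )
        sets[name] = GeneSet(
            name, "planted-program reference set",
            frozenset(included.tolist()) | frozenset(pad.tolist()),
        )
        size_match = len(sets[name])
        for d in range(n_decoys_per_program):
            n_take = min(size_match, nonmembers.size)
            if n_take == 0:  # program spans the whole universe: no decoy possible
                continue
            decoy = rng.choice(nonmembers, size=n_take, replace=False)
            sets[f"decoy_{name}_{d + 1}"] = GeneSet(
                f"decoy_{name}_{d + 1}", "size-matched decoy set",
                frozenset(decoy.tolist()),
            )
    if not sets:
        raise ValidationError("truth frame contains no program members")
    return GeneSetCollection(sets, source_label="synthetic_reference")


def random_gene_sets(
    genes: list[str] | np.ndarray,
    n_sets: int,
    size: int,
    rng: np.random.Generator,
    prefix: str = "decoy",
) -> GeneSetCollection:
    """Uniformly drawn gene sets — the null construction for calibration."""
    genes = np.asarray(genes)
    if size > genes.size:
        raise ValidationError("set size exceeds the gene universe")
    sets = {}
    for i in range(n_sets):
        name = f"{prefix}_{i + 1:03d}"
        members = rng.choice(genes, size=size, replace=False)
        sets[name] = GeneSet(name, "random set", frozenset(members.tolist()))
    return GeneSetCollection(sets, source_label="random")


def simulate_comparison_bank(
    config: GenerativeConfig,
    n_sharing: int,
    n_null: int,
    sharing_prefix: str = "S",
    null_prefix: str = "N",
) -> tuple[DETable, OrthologMap, list[tuple[str, DETable, bool]]]:
    """A reference study plus a bank of comparison studies.

    ``n_sharing`` comparisons share the reference's planted programs
    (identical true effects, independent noise); ``n_null`` comparisons carry
    no planted signal at all.  Returns the species-A reference table, the
    ortholog map, and ``(comparison_id, table_b, shares)`` triples, the ids
    numbered within each group.  Used to emulate ranking a disease panel
    against a single perturbation signature.
    """
    if n_sharing < 0 or n_null < 0 or n_sharing + n_null == 0:
        raise ValidationError("need at least one comparison")
    rng = np.random.default_rng(config.seed)
    membership = _membership(config)
    genes_a = gene_names(config.n_genes)
    effects = _draw_effects(config, membership, rng)
    beta_a = _beta(config, membership, effects)
    table_a = _observe(config, beta_a, genes_a, "reference", Species.synthetic, rng)

    n_mapped = max(int(round(config.ortholog_coverage * config.n_genes)), 1)
    mapped = np.sort(rng.choice(config.n_genes, size=n_mapped, replace=False))
    symbols_b, pairs = _species_b_symbols(genes_a, mapped)
    omap = OrthologMap(sorted(pairs), Species.synthetic, Species.synthetic)

    beta_null = np.zeros(config.n_genes)
    comparisons: list[tuple[str, DETable, bool]] = []
    for i in range(n_sharing):
        cid = f"{sharing_prefix}{i + 1:02d}"
        comparisons.append(
            (cid, _observe(config, beta_a, symbols_b, cid, Species.synthetic, rng),
             True)
        )
    for i in range(n_null):
        cid = f"{null_prefix}{i + 1:02d}"
        comparisons.append(
            (cid, _observe(config, beta_null, symbols_b, cid, Species.synthetic, rng),
             False)
        )
    return table_a, omap, comparisons
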