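"""Pathway presence calling and quinone x dehydrogenase co-occurrence.

Species are classified from the presence/absence of 13 marker genes:

* classical naphthoquinone (NQ, menaquinone) biosynthesis: menB, menC, menF
* futalosine NQ biosynthesis: mqnA, mqnC, mqnD
* ubiquinone (UQ) biosynthesis: ubiA, ubiC, ubiG
* type-I NADH dehydrogenase (NDH-1, nuo operon): nuoA, nuoE, nuoJ
* type-II NADH dehydrogenase (NDH-2): ndh

A pathway variant is called present when its representative genes satisfy
the presence rule (default: all of them present); the NQ flag is the OR of
the classical and futalosine variants.  The co-occurrence table counts
species per (quinone category) x (dehydrogenase category) cell and reports
the two headline fractions: the fraction of NQ species that also carry
NDH-2 (exclusively or together with NDH-1), and the fraction of species in
which NDH-2 coexists with UQ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PATHWAY_GENES: dict[str, tuple[str, ...]] = {
    "nq_classical": ("menB", "menC", "menF"),
    "nq_futalosine": ("mqnA", "mqnC", "mqnD"),
    "uq": ("ubiA", "ubiC", "ubiG"),
    "ndh1": ("nuoA", "nuoE", "nuoJ"),
    "ndh2": ("ndh",),
}

#: The 13-gene marker panel, in panel order.
PANEL_GENES: tuple[str, ...] = tuple(
    g for genes in PATHWAY_GENES.values() for g in genes
)

QUINONE_CATEGORIES = ("NQ-only", "UQ-only", "both", "neither")
DH_CATEGORIES = ("NDH1-only", "NDH2-only", "both", "neither")


@dataclass
class PathwayScheme:
    """Gene panels and the presence rule used to call each pathway.

    presence_rule is ``"all"`` (every representative gene required) or
    ``"at_least_k"`` for an integer k (e.g. ``"at_least_2"``).
    """

    pathway_genes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(PATHWAY_GENES)
    )
    presence_rule: str = "all"

    def required_count(self, pathway: str) -> int:
        n = len(self.pathway_genes[pathway])
        if self.presence_rule == "all":
            return n
        if self.presence_rule.startswith("at_least_"):
            k = int(self.presence_rule.rsplit("_", 1)[1])
            return min(k, n)
        raise ValueError(f"unknown presence rule {self.presence_rule!r}")

    @property
    def panel_genes(self) -> tuple[str, ...]:
        return tuple(g for genes in self.pathway_genes.values() for g in genes)


@dataclass(frozen=True)
class PathwayCall:
    """Per-species pathway flags and the derived categories."""

    species_id: str
    nq_classical: bool
    nq_futalosine: bool
    uq: bool
    ndh1: bool
    ndh2: bool

    @property
    def nq(self) -> bool:
        return self.nq_classical or self.nq_futalosine

    @property
    def quinone_category(self) -> str:
        if self.nq and self.uq:
            return "both"
        if self.nq:
            return "NQ-only"
        if self.uq:
            return "UQ-only"
        return "neither"

    @property
    def dh_category(self) -> str:
        if self.ndh1 and self.ndh2:
            return "both"
        if self.ndh1:
            return "NDH1-only"
        if self.ndh2:
            return "NDH2-only"
        return "neither"


@dataclass
class CooccurrenceTable:
    """Quinone-category x dehydrogenase-category counts and fractions.

    ``frac_nq_with_ndh2`` is |NQ and NDH2| / |NQ| (NaN when no species has
    the NQ pathway).  ``frac_ndh2_with_uq`` is |UQ and NDH2| divided by the
    configured denominator (all species by default); the alternative
    denominators are reported side by side in :meth:`summary`.
    """

    counts: pd.DataFrame  # index: quinone categories, columns: dh categories
    n_species: int
    frac_nq_with_ndh2: float
    frac_ndh2_with_uq: float
    ndh2_uq_denominator: str = "all"
    alt_fractions: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_species": self.n_species,
            "frac_nq_with_ndh2": self.frac_nq_with_ndh2,
            "frac_ndh2_with_uq": self.frac_ndh2_with_uq,
            "ndh2_uq_denominator": self.ndh2_uq_denominator,
            "alt_fractions": self.alt_fractions,
            "counts": {
                q: {d: int(self.counts.loc[q, d]) for d in DH_CATEGORIES}
                for q in QUINONE_CATEGORIES
            },
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def to_long_tsv(self, path: str | Path) -> None:
        """Long-format table (quinone_category, dh_category, count)."""
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["quinone_category", "dh_category", "count"]
        long.to_csv(path, sep="\t", index=False)


def call_pathways(
    presence: Mapping[str, bool],
    scheme: PathwayScheme | None = None,
    species_id: str = "",
) -> PathwayCall:
    """Apply the presence rule to per-gene presence flags.

    ``presence`` must define every panel gene of the scheme; missing genes
    are an input error (absence must be stated explicitly, not implied).
    """
    scheme = scheme or PathwayScheme()
    missing = [g for g in scheme.panel_genes if g not in presence]
    if missing:
        raise KeyError(f"presence is missing panel genes: {missing}")
    flags = {}
    for pathway, genes in scheme.pathway_genes.items():
        n_present = sum(bool(presence[g]) for g in genes)
        flags[pathway] = n_present >= scheme.required_count(pathway)
    return PathwayCall(
        species_id=species_id,
        nq_classical=flags["nq_classical"],
        nq_futalosine=flags["nq_futalosine"],
        uq=flags["uq"],
        ndh1=flags["ndh1"],
        ndh2=flags["ndh2"],
    )


def tabulate_cooccurrence(
    calls: Sequence[PathwayCall],
    ndh2_uq_denominator: str = "all",
) -> CooccurrenceTable:
    """Count species per (quinone, dehydrogenase) category and compute the
    headline fractions.

    ``ndh2_uq_denominator`` selects the denominator of the UQ-with-NDH2
    fraction: ``"all"`` (all analysed species), ``"ndh2"`` (NDH-2 species)
    or ``"uq"`` (UQ species).  All three are reported in ``alt_fractions``.
    """
    if not calls:
        raise ValueError("tabulate_cooccurrence requires at least one call")
    counts = pd.DataFrame(
        0, index=list(QUINONE_CATEGORIES), columns=list(DH_CATEGORIES), dtype=int
    )
    n_nq = n_nq_ndh2 = n_uq = n_ndh2 = n_uq_ndh2 = 0
    for c in calls:
        counts.loc[c.quinone_category, c.dh_category] += 1
        if c.nq:
            n_nq += 1
            if c.ndh2:
                n_nq_ndh2 += 1
        if c.uq:
            n_uq += 1
        if c.ndh2:
            n_ndh2 += 1
        if c.uq and c.ndh2:
            n_uq_ndh2 += 1
    n = len(calls)
    frac_nq_with_ndh2 = n_nq_ndh2 / n_nq if n_nq else float("nan")
    denominators = {
        "all": n,
        "ndh2": n_ndh2,
        "uq": n_uq,
    }
    alt = {
        key: (n_uq_ndh2 / d if d else float("nan"))
        for key, d in denominators.items()
    }
    if ndh2_uq_denominator not in denominators:
        raise ValueError(f"unknown denominator {ndh2_uq_denominator!r}")
    return CooccurrenceTable(
        counts=counts,
        n_species=n,
        frac_nq_with_ndh2=frac_nq_with_ndh2,
        frac_ndh2_with_uq=alt[ndh2_uq_denominator],
        ndh2_uq_denominator=ndh2_uq_denominator,
        alt_fractions=alt,
    )


# ---------------------------------------------------------------------------
# Recomputation from a per-genome search-result sheet
# ---------------------------------------------------------------------------


def _load_sheet(sheet) -> pd.DataFrame:
    if isinstance(sheet, pd.DataFrame):
        return sheet
    path = Path(sheet)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def presence_from_hits(
    hits: pd.DataFrame,
    thresholds=None,
    panel_genes: Sequence[str] = PANEL_GENES,
) -> pd.DataFrame:
    """Wide per-genome presence table from a long hit table.

    ``hits`` needs columns genome_id, species_id, gene and either a
    boolean ``present`` column or ``bit_score``/``evalue`` columns to which
    the filtering rule (gene-specific E-value cutoff and minimum bit
    score) is applied.
    """
    from .search import GeneThresholds  # local import to avoid a cycle

    df = hits.copy()
    if "present" not in df.columns:
        th = thresholds or GeneThresholds()
        if not {"bit_score", "evalue"} <= set(df.columns):
            raise ValueError(
                "hit table needs a 'present' column or 'bit_score' and "
                f"'evalue' columns; got {sorted(df.columns)}"
            )
        df["present"] = [
            th.passes(g, b, e)
            for g, b, e in zip(df["gene"], df["bit_score"], df["evalue"])
        ]
    keep = df[df["present"].astype(bool)]
    genomes = df[["genome_id", "species_id"]].drop_duplicates("genome_id")
    wide = pd.DataFrame(False, index=genomes["genome_id"], columns=list(panel_genes))
    for genome_id, gene in zip(keep["genome_id"], keep["gene"]):
        if gene in wide.columns:
            wide.loc[genome_id, gene] = True
    wide.insert(0, "species_id", genomes.set_index("genome_id")["species_id"])
    return wide.reset_index()


def recompute_from_sheet(
    sheet,
    scheme: PathwayScheme | None = None,
    thresholds=None,
    collapse_rule: str = "any",
    ndh2_uq_denominator: str = "all",
    drop_double_negative: bool = False,
) -> CooccurrenceTable:
    """Recompute the co-occurrence statistics from a search-result sheet.

    Accepts either layout:

    * wide: one row per genome with columns ``genome_id``, ``species_id``
      and one boolean column per panel gene;
    * long: one row per hit with columns ``genome_id``, ``species_id``,
      ``gene`` and either ``present`` or raw ``bit_score``/``evalue``
      scores (filtered with ``thresholds``).

    Genomes are collapsed to species with ``collapse_rule`` (any/majority/
    all), pathways called under ``scheme`` and tabulated.  With
    ``drop_double_negative`` species carrying neither quinone pathway nor
    either dehydrogenase are removed before tabulation.
    """
    from .search import collapse_to_species

    scheme = scheme or PathwayScheme()
    df = _load_sheet(sheet)
    panel = scheme.panel_genes
    cols = set(df.columns)
    if {"genome_id", "species_id"} - cols:
        raise ValueError(
            "sheet must carry genome_id and species_id columns; "
            f"found columns {sorted(cols)}"
        )
    if set(panel) <= cols:  # wide presence layout
        wide = df[["genome_id", "species_id", *panel]].copy()
    elif "gene" in cols:  # long hit layout
        wide = presence_from_hits(df, thresholds=thresholds, panel_genes=panel)
    else:
        raise ValueError(
            "unrecognised sheet layout: expected per-gene presence columns "
            f"{list(panel)} or a long table with a 'gene' column; "
            f"found columns {sorted(cols)}"
        )
    species = collapse_to_species(wide, rule=collapse_rule, panel_genes=panel)
    calls = [
        call_pathways(
            {g: bool(row[g]) for g in panel}, scheme, species_id=str(row["species_id"])
        )
        for _, row in species.iterrows()
    ]
    if drop_double_negative:
        calls = [
            c for c in calls
            if not (c.quinone_category == "neither" and c.dh_category == "neither")
        ]
        if not calls:
            raise ValueError("all species dropped as double-negative")
    return tabulate_cooccurrence(calls, ndh2_uq_denominator=ndh2_uq_denominator)


def sensitivity_sweep(
    sheet,
    presence_rules: Iterable[str] = ("all", "at_least_2"),
    collapse_rules: Iterable[str] = ("any", "majority", "all"),
    denominators: Iterable[str] = ("all", "ndh2", "uq"),
    thresholds=None,
) -> pd.DataFrame:
    """Recompute the headline statistics under every rule combination.

    Returns one row per (presence_rule, collapse_rule, denominator) with
    n_species and both fractions, for judging which configuration matches
    a reported statistic.
    """
    rows = []
    for prule in presence_rules:
        for crule in collapse_rules:
            for denom in denominators:
                table = recompute_from_sheet(
                    sheet,
                    scheme=PathwayScheme(presence_rule=prule),
                    thresholds=thresholds,
                    collapse_rule=crule,
                    ndh2_uq_denominator=denom,
                )
                rows.append(
                    {
                        "presence_rule": prule,
                        "collapse_rule": crule,
                        "ndh2_uq_denominator": denom,
                        "n_species": table.n_species,
                        "frac_nq_with_ndh2": table.frac_nq_with_ndh2,
                        "frac_ndh2_with_uq": table.frac_ndh2_with_uq,
                    }
                )
    return pd.DataFrame(rows)
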