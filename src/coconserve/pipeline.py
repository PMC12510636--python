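"""End-to-end convenience wiring: cluster -> build -> calibrate -> search
-> call -> tabulate.

These helpers chain the individual stages with their defaults so the whole
co-conservation analysis runs in a couple of calls, both in tests and from
the command line.  Each stage remains independently usable.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .cooccurrence import (
    CooccurrenceTable,
    PathwayScheme,
    call_pathways,
    tabulate_cooccurrence,
)
from .profilehmm import ProfileHMM, build_profile, calibrate_evalue
from .search import GeneThresholds, Hit, collapse_to_species, search_proteomes
from .seqcluster import ClusterParams, cluster_at_identity, subset_alignment
from .synthetic import Family, SpeciesSet


def build_marker_profiles(
    families: Mapping[str, Family],
    identity_threshold: float = 0.50,
    pseudocount: float = 1.0,
    gap_fraction_cutoff: float = 0.5,
    n_random: int = 1000,
    db_size: int = 1000,
    seed: int = 0,
) -> dict[str, ProfileHMM]:
    """De-redundify each family at the identity threshold, build a profile
    from the cluster representatives' alignment, and calibrate E-values.

    Representatives are taken from greedy clustering of the family members
    (the master is held out as the generating ancestor, not an observed
    sequence); the profile is built on the true alignment restricted to
    the representatives.
    """
    params = ClusterParams(identity_threshold=identity_threshold)
    profiles: dict[str, ProfileHMM] = {}
    for i, (gene, family) in enumerate(sorted(families.items())):
        clustering = cluster_at_identity(family.members, params)
        rep_rows = subset_alignment(family.msa, clustering.representative_ids)
        profile = build_profile(
            rep_rows,
            pseudocount=pseudocount,
            gap_fraction_cutoff=gap_fraction_cutoff,
            name=gene,
        )
        calibrate_evalue(
            profile,
            n_random=n_random,
            db_size=db_size,
            seed=(seed * 613 + i * 31) % (2**31),
        )
        profiles[gene] = profile
    return profiles


def run_cooccurrence_pipeline(
    species_set: SpeciesSet,
    profiles: Mapping[str, ProfileHMM],
    thresholds: GeneThresholds | None = None,
    scheme: PathwayScheme | None = None,
    collapse_rule: str = "any",
    ndh2_uq_denominator: str = "all",
) -> tuple[list[Hit], pd.DataFrame, CooccurrenceTable]:
    """Search every generated proteome and tabulate co-occurrence.

    Returns (hits, species-level presence table, co-occurrence table).
    """
    scheme = scheme or PathwayScheme()
    hits, genome_presence = search_proteomes(profiles, species_set.proteomes, thresholds)
    species_presence = collapse_to_species(
        genome_presence, rule=collapse_rule, panel_genes=scheme.panel_genes
    )
    calls = [
        call_pathways(
            {g: bool(row[g]) for g in scheme.panel_genes},
            scheme,
            species_id=str(row["species_id"]),
        )
        for _, row in species_presence.iterrows()
    ]
    table = tabulate_cooccurrence(calls, ndh2_uq_denominator=ndh2_uq_denominator)
    return hits, species_presence, table


def presence_accuracy(
    species_presence: pd.DataFrame, truth: pd.DataFrame, panel_genes=None
) -> float:
    """Fraction of correctly recovered gene presence flags vs the planted
    truth, over all (species, gene) cells."""
    from .cooccurrence import PANEL_GENES

    genes = list(panel_genes) if panel_genes is not None else list(PANEL_GENES)
    pred = species_presence.set_index("species_id")[genes].astype(bool)
    true = truth.set_index("species_id")[genes].astype(bool)
    pred, true = pred.align(true, join="inner")
    if pred.empty:
        raise ValueError("no overlapping species between prediction and truth")
    return float((pred.to_numpy() == true.to_numpy()).mean())
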