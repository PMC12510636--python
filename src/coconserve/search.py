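"""Panel homology search over proteomes and the hit-filtering rule.

Every sequence of a proteome is scored against every marker profile; a hit
is retained when its E-value is at or below the gene-specific cutoff AND
its bit score is at least the minimum (100 bits by default, inclusive).
The best retained hit per (genome, gene) sets the presence flag.  Genome
level presence is collapsed to species level with a configurable rule
(any / majority / all).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .cooccurrence import PANEL_GENES
from .profilehmm import ProfileHMM, _forward_kernel, _forward_args, LN2, encode_sequence, evalue
from .seqcluster import SequenceRecord, read_fasta

logger = logging.getLogger(__name__)

#: Conservative default per-gene E-value cutoff used when a gene is not
#: listed in the thresholds table.
DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_MIN_BIT_SCORE = 100.0


@dataclass
class GeneThresholds:
    """Gene-specific E-value cutoffs plus the global minimum bit score.

    Both filters are inclusive: a hit passes with evalue <= cutoff and
    bit_score >= min_bit_score.
    """

    evalue_by_gene: dict[str, float] = field(default_factory=dict)
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE
    default_evalue: float = DEFAULT_EVALUE_CUTOFF

    def __post_init__(self) -> None:
        for gene, cutoff in self.evalue_by_gene.items():
            if cutoff <= 0:
                raise ValueError(f"E-value cutoff for {gene} must be > 0")
        if self.default_evalue <= 0:
            raise ValueError("default E-value cutoff must be > 0")

    def cutoff(self, gene: str) -> float:
        return self.evalue_by_gene.get(gene, self.default_evalue)

    def passes(self, gene: str, bit_score: float, ev: float) -> bool:
        return ev <= self.cutoff(gene) and bit_score >= self.min_bit_score

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneThresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            evalue_by_gene={str(k): float(v) for k, v in (data.get("evalue_by_gene") or {}).items()},
            min_bit_score=float(data.get("min_bit_score", DEFAULT_MIN_BIT_SCORE)),
            default_evalue=float(data.get("default_evalue", DEFAULT_EVALUE_CUTOFF)),
        )

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "GeneThresholds":
        """Two-column table (gene, evalue_cutoff), with or without header."""
        df = pd.read_csv(path, sep="\t")
        if "gene" not in df.columns:
            df = pd.read_csv(path, sep="\t", header=None, names=["gene", "evalue_cutoff"])
        col = "evalue_cutoff" if "evalue_cutoff" in df.columns else df.columns[1]
        return cls(
            evalue_by_gene=dict(zip(df["gene"].astype(str), df[col].astype(float))),
            **kwargs,
        )


@dataclass(frozen=True)
class Hit:
    """One retained profile-vs-sequence match."""

    genome_id: str
    species_id: str
    gene: str
    sequence_id: str
    bit_score: float
    evalue: float


@dataclass
class GenomePresence:
    genome_id: str
    species_id: str
    present: dict[str, bool]


def parse_header(record: SequenceRecord) -> tuple[str, str]:
    """Extract (genome_id, species_id) from a ``genomeID|speciesID|label``
    header; a header without the dialect maps to (id, id)."""
    parts = record.id.split("|")
    if len(parts) >= 2:
        return parts[0], parts[1]
    return record.id, record.id


def search_proteome(
    profiles: Mapping[str, ProfileHMM],
    proteome: Sequence[SequenceRecord] | str | Path,
    thresholds: GeneThresholds | None = None,
    genome_id: str | None = None,
    species_id: str | None = None,
    db_size: int | None = None,
) -> tuple[list[Hit], GenomePresence]:
    """Score one proteome against the calibrated marker-profile panel.

    E-values use ``db_size`` = the number of sequences in this proteome
    unless overridden.  An empty proteome yields no hits and all-false
    presence.  A sequence retained by more than one profile is logged as a
    warning and kept for both genes (no cross-gene competition).
    """
    thresholds = thresholds or GeneThresholds()
    records = read_fasta(proteome) if isinstance(proteome, (str, Path)) else list(proteome)
    for gene, prof in profiles.items():
        if prof.calibration is None:
            raise ValueError(f"profile for {gene} is not calibrated")
    if records:
        g0, s0 = parse_header(records[0])
    else:
        g0 = s0 = ""
    genome_id = genome_id if genome_id is not None else g0
    species_id = species_id if species_id is not None else s0
    db = db_size if db_size is not None else max(len(records), 1)

    best: dict[str, Hit] = {}
    genes_per_seq: dict[str, list[str]] = {}
    encoded = [encode_sequence(r.residues) for r in records]
    for gene, prof in profiles.items():
        args = _forward_args(prof)
        cutoff = thresholds.cutoff(gene)
        for rec, x in zip(records, encoded):
            bits = float(_forward_kernel(x, *args)) / LN2
            if bits < thresholds.min_bit_score:
                continue
            ev = evalue(prof, bits, db_size=db)
            if ev > cutoff:
                continue
            prev = best.get(gene)
            if prev is None or bits > prev.bit_score:
                best[gene] = Hit(
                    genome_id=genome_id,
                    species_id=species_id,
                    gene=gene,
                    sequence_id=rec.id,
                    bit_score=bits,
                    evalue=ev,
                )
            genes_per_seq.setdefault(rec.id, []).append(gene)
    for seq_id, genes in genes_per_seq.items():
        if len(genes) > 1:
            logger.warning(
                "sequence %s satisfies %d profiles (%s); all retained",
                seq_id, len(genes), ", ".join(genes),
            )
    present = {g: g in best for g in profiles}
    hits = sorted(best.values(), key=lambda h: h.gene)
    return hits, GenomePresence(genome_id=genome_id, species_id=species_id, present=present)


def search_proteomes(
    profiles: Mapping[str, ProfileHMM],
    proteomes: Mapping[str, Sequence[SequenceRecord]] | Iterable[str | Path],
    thresholds: GeneThresholds | None = None,
) -> tuple[list[Hit], pd.DataFrame]:
    """Search a set of proteomes; returns all hits and a wide presence
    table (one row per genome, one boolean column per gene)."""
    all_hits: list[Hit] = []
    rows = []
    items: Iterable
    if isinstance(proteomes, Mapping):
        items = proteomes.items()
    else:
        items = ((None, p) for p in proteomes)
    for gid, proteome in items:
        hits, presence = search_proteome(
            profiles, proteome, thresholds, genome_id=gid if isinstance(gid, str) else None
        )
        all_hits.extend(hits)
        rows.append(
            {"genome_id": presence.genome_id, "species_id": presence.species_id,
             **{g: presence.present.get(g, False) for g in profiles}}
        )
    return all_hits, pd.DataFrame(rows)


def hits_to_tsv(hits: Sequence[Hit], path: str | Path) -> None:
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(path, sep="\t", index=False)


def presence_to_tsv(presence: pd.DataFrame, path: str | Path) -> None:
    presence.to_csv(path, sep="\t", index=False)


def collapse_to_species(
    presences: pd.DataFrame | Sequence[GenomePresence],
    rule: str = "any",
    panel_genes: Sequence[str] = PANEL_GENES,
) -> pd.DataFrame:
    """Collapse genome-level presence to species level.

    ``rule``: ``any`` (gene present in >= 1 genome of the species),
    ``all`` (in every genome) or ``majority`` (in strictly more than half).
    """
    if not isinstance(presences, pd.DataFrame):
        if not presences:
            raise ValueError("collapse_to_species requires at least one genome")
        presences = pd.DataFrame(
            [
                {"genome_id": p.genome_id, "species_id": p.species_id, **p.present}
                for p in presences
            ]
        )
    if presences.empty:
        raise ValueError("collapse_to_species requires at least one genome")
    genes = [g for g in panel_genes if g in presences.columns]
    grouped = presences.groupby("species_id")[genes]
    if rule == "any":
        out = grouped.any()
    elif rule == "all":
        out = grouped.all()
    elif rule == "majority":
        out = grouped.mean() > 0.5
    else:
        raise ValueError(f"unknown collapse rule {rule!r}")
    return out.reset_index()
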